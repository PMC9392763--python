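"""Control-based scaling and time-zero normalisation.

Every downstream spectrum starts here: viability fluorescence is expressed
as percent of the lysed -> dark control range, and ECIS traces are scaled
per time point between the no-cell (0) and dark (1) control traces before
division by their time-zero value.
"""

from __future__ import annotations

import numpy as np

from actinospec.plate_io import EcisTrace, PlateMap, ViabilityPlate, WellRole

__all__ = [
    "DegenerateControlsError",
    "minmax_scale",
    "scale_viability_plate",
    "t0_normalize",
    "scale_ecis",
    "mean_trace",
]


class DegenerateControlsError(ValueError):
    """Positive and negative control references coincide (zero dynamic range)."""


def minmax_scale(x, min_ref: float, max_ref: float):
    """Affine percent-of-control scaling: ``((x - MIN)/(MAX - MIN)) * 100``.

    ``min_ref`` (positive control) maps to 0, ``max_ref`` (negative/dark
    control) to 100. Values outside the control range are *not* clipped:
    they carry real signal (e.g. hormetic responses) and clipping would
    bias downstream slope fits.
    """
    if max_ref <= min_ref:
        raise DegenerateControlsError(
            f"control range degenerate: min_ref={min_ref}, max_ref={max_ref}"
        )
    return (np.asarray(x, dtype=float) - min_ref) / (max_ref - min_ref) * 100.0


def scale_viability_plate(plate: ViabilityPlate, pmap: PlateMap) -> dict[str, float]:
    """Scale every non-control well between the plate's own control means.

    min reference = mean of lysed (fully dead) wells; max reference = mean
    of dark (no-UVR) wells; replicate control wells are averaged
    arithmetically.
    """
    lysed = [plate.readings[r.well] for r in pmap.by_role(WellRole.LYSED_CONTROL) if r.well in plate.readings]
    dark = [plate.readings[r.well] for r in pmap.by_role(WellRole.DARK_CONTROL) if r.well in plate.readings]
    if not lysed or not dark:
        raise ValueError(
            f"plate {plate.plate_id}: needs >=1 lysed_control and >=1 dark_control well with readings"
        )
    min_ref = float(np.mean(lysed))
    max_ref = float(np.mean(dark))
    out = {}
    for rec in pmap.by_role(WellRole.EXPOSED):
        if rec.well in plate.readings:
            out[rec.well] = float(minmax_scale(plate.readings[rec.well], min_ref, max_ref))
    return out


def t0_normalize(trace: EcisTrace) -> EcisTrace:
    """Divide each electrical parameter by its first (time-zero) sample."""
    if trace.n_samples == 0:
        raise ValueError(f"trace {trace.well}: empty")
    arrays = {}
    for param, attr in EcisTrace._PARAMS.items():
        v = getattr(trace, attr)
        if v[0] <= 0:
            raise ValueError(f"trace {trace.well}: t0 {param} value {v[0]} is not positive")
        arrays[attr] = v / v[0]
    out = trace.replace_values(**arrays)
    out.normalized = True
    out.meta.setdefault("ops", []).append("t0_normalize")
    return out


def _align_indices(target_t: np.ndarray, source_t: np.ndarray, max_gap_h: float) -> np.ndarray:
    """Nearest-sample alignment of source onto target times (max gap bounded)."""
    idx = np.searchsorted(source_t, target_t)
    idx = np.clip(idx, 1, len(source_t) - 1) if len(source_t) > 1 else np.zeros_like(idx)
    left = np.maximum(idx - 1, 0)
    choose_left = np.abs(source_t[left] - target_t) <= np.abs(source_t[idx] - target_t)
    nearest = np.where(choose_left, left, idx)
    gaps = np.abs(source_t[nearest] - target_t)
    if np.any(gaps > max_gap_h):
        worst = float(gaps.max())
        raise ValueError(
            f"control trace cannot be aligned: max time gap {worst:.3f} h exceeds {max_gap_h:.3f} h"
        )
    return nearest


def scale_ecis(
    trace: EcisTrace,
    no_cell_ctrl: EcisTrace,
    dark_ctrl: EcisTrace,
    max_gap_h: float = 11.0 / 60.0,
    t0_first: bool = False,
) -> EcisTrace:
    """Scale a trace between the no-cell (-> 0) and dark (-> 1) controls.

    Scaling is per time point on a fraction scale (no x100), aligned to the
    data trace's grid by nearest control sample (gap at most one sampling
    interval), followed by time-zero normalisation. ``t0_first=True``
    reverses the order for sensitivity analysis.
    """
    ops = []
    if t0_first:
        trace = t0_normalize(trace)
        no_cell_ctrl = t0_normalize(no_cell_ctrl)
        dark_ctrl = t0_normalize(dark_ctrl)
        ops.append("t0_normalize")
    nc_idx = _align_indices(trace.time_h, no_cell_ctrl.time_h, max_gap_h)
    dk_idx = _align_indices(trace.time_h, dark_ctrl.time_h, max_gap_h)
    arrays = {}
    for param, attr in EcisTrace._PARAMS.items():
        x = getattr(trace, attr)
        lo = getattr(no_cell_ctrl, attr)[nc_idx]
        hi = getattr(dark_ctrl, attr)[dk_idx]
        span = hi - lo
        bad = np.isclose(span, 0.0)
        if np.any(bad):
            t_bad = trace.time_h[bad][0]
            raise DegenerateControlsError(
                f"trace {trace.well}, {param}: controls coincide at t={t_bad:.3f} h"
            )
        arrays[attr] = (x - lo) / span
    ops.append("minmax_scale")
    out = trace.replace_values(normalized=True, **arrays)
    if not t0_first:
        frac0 = {attr: arrays[attr][0] for attr in arrays}
        for attr, v0 in frac0.items():
            if v0 <= 0:
                raise ValueError(f"trace {trace.well}: scaled t0 value {v0} not positive")
            arrays[attr] = arrays[attr] / v0
        out = out.replace_values(normalized=True, **arrays)
        ops.append("t0_normalize")
    out.meta["ops"] = ops
    return out


def mean_trace(traces: list[EcisTrace], label: str = "mean") -> EcisTrace:
    """Average replicate traces sample-wise (common grid required)."""
    if not traces:
        raise ValueError("no traces to average")
    t0 = traces[0].time_h
    for tr in traces[1:]:
        if len(tr.time_h) != len(t0) or not np.allclose(tr.time_h, t0):
            raise ValueError("traces must share a common time grid to be averaged")
    return EcisTrace(
        well=label,
        frequency_hz=traces[0].frequency_hz,
        time_h=t0.copy(),
        impedance_ohm=np.mean([tr.impedance_ohm for tr in traces], axis=0),
        resistance_ohm=np.mean([tr.resistance_ohm for tr in traces], axis=0),
        capacitance_f=np.mean([tr.capacitance_f for tr in traces], axis=0),
        normalized=all(tr.normalized for tr in traces),
    )
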