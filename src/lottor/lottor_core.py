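"""The missing-wedge restoration algorithm.

Starting from a reconstruction whose Fourier transform F₀ is only known on
the measured data zone, the algorithm alternates two projections:

* **real space** — outside a support mask the density is reset to zero;
  inside, imaginary parts are discarded and negative values clamped to
  zero;
* **Fourier space** — on the data zone the transform is locked back to F₀
  (the measured data are never altered); only the missing-wedge voxels
  remain free variables.

One iteration is one such cycle; a *round* is ``n_iter_per_round``
iterations (default 1,000) under a fixed mask.  After each round the mask
is regenerated from the round's output, which typically has less
z-elongation than the initial map and therefore constrains the next round
better.  The mask itself is the isosurface of a heavily low-pass-filtered
map (default 40 Å), thresholded so its volume equals ``volume_factor``
(default 3) times the protein's molecular-weight-equivalent volume at
1.21 Å³/Da.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._fourier import cfftn, icfftn
from .io_maps import DensityMap
from .metrics import lowpass
from .phantom import V_PER_DA
from .tomo_sim import DataZone, make_data_zone

logger = logging.getLogger(__name__)


@dataclass
class Mask:
    """Boolean real-space support with its provenance."""

    membership: np.ndarray
    filter_res: float           # Å used to smooth the source map
    volume_factor: float        # mask volume / MW-equivalent volume
    threshold: float            # density cutoff in the filtered map
    source: str = "initial"     # initial | round_k | object

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if not self.membership.any():
            raise ValueError("mask is empty")
        if self.membership.all():
            raise ValueError("mask covers the whole box")

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.membership))


@dataclass
class LottorParams:
    """Restoration parameters.

    ``mask_filter_res`` 40–80 Å and ``volume_factor`` ~1.5–4 are the useful
    ranges; 1,000 iterations per round for 5 rounds is the standard recipe.
    """

    tilt_max: float
    mw_da: float
    voxel_size: float
    mask_filter_res: float = 40.0
    volume_factor: float = 3.0
    n_iter_per_round: int = 1000
    n_rounds: int = 5
    v_per_da: float = V_PER_DA
    mask_override: Mask | None = None
    early_stop_tol: float | None = None  # default: fixed iteration count

    def __post_init__(self) -> None:
        if not 0 < self.tilt_max <= 90:
            raise ValueError("tilt_max must be in (0, 90]")
        if self.mw_da <= 0:
            raise ValueError("mw_da must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.n_iter_per_round < 1:
            raise ValueError("n_iter_per_round must be >= 1")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")


@dataclass
class RestorationResult:
    """Output of :func:`run_lottor`."""

    final_map: DensityMap
    per_round_maps: list[DensityMap]
    convergence: list[np.ndarray]   # per-round traces of relative change
    params: LottorParams
    masks: list[Mask] = field(default_factory=list)


def make_mask(density_map: DensityMap, params: LottorParams,
              source: str = "initial") -> Mask:
    """Threshold a low-pass-filtered map at a calibrated volume.

    The map is filtered to ``params.mask_filter_res``; bisection then finds
    the density threshold whose above-threshold voxel count matches the
    target volume ``volume_factor × mw_da × v_per_da`` within 1%.
    """
    if not np.any(density_map.values):
        raise ValueError("cannot build a mask from an all-zero map")
    target_voxels = (params.volume_factor * params.mw_da * params.v_per_da
                     / density_map.voxel_size**3)
    n_total = density_map.values.size
    if target_voxels >= n_total:
        raise ValueError(
            f"target mask volume ({target_voxels:.3g} voxels) exceeds the "
            f"box ({n_total} voxels)"
        )
    filtered = lowpass(density_map, params.mask_filter_res).values
    lo = float(filtered.min())
    hi = float(filtered.max())
    count_at_lo = n_total  # everything above min
    if count_at_lo < target_voxels:
        raise ValueError(
            f"cannot bracket the target volume: at most {count_at_lo} voxels "
            f"available, {target_voxels:.0f} requested"
        )
    threshold = 0.5 * (lo + hi)
    for _ in range(80):
        threshold = 0.5 * (lo + hi)
        count = int(np.count_nonzero(filtered >= threshold))
        if abs(count - target_voxels) <= 0.01 * target_voxels:
            break
        if count > target_voxels:
            lo = threshold
        else:
            hi = threshold
    else:
        count = int(np.count_nonzero(filtered >= threshold))
        achievable = (int(np.count_nonzero(filtered >= hi)),
                      int(np.count_nonzero(filtered >= lo)))
        raise ValueError(
            f"bisection failed to reach the target volume within 1%: "
            f"wanted {target_voxels:.0f} voxels, bracket reaches "
            f"{achievable[0]}–{achievable[1]}"
        )
    return Mask(filtered >= threshold, params.mask_filter_res,
                params.volume_factor, threshold, source)


def apply_real_constraints(values: np.ndarray | DensityMap,
                           mask: Mask) -> np.ndarray:
    """Support, realness and non-negativity constraints on one volume.

    Outside the mask the density is zero; inside, the imaginary part is
    discarded and negative real values are clamped to zero.  Accepts the
    complex volume produced by an inverse transform; returns a real array.
    """
    if isinstance(values, DensityMap):
        values = values.values
    if values.shape != mask.membership.shape:
        raise ValueError(
            f"grid mismatch: map {values.shape} vs mask "
            f"{mask.membership.shape}"
        )
    real = np.real(values)
    return np.where(mask.membership, np.maximum(real, 0.0), 0.0)


def replace_data_zone(current: np.ndarray, original: np.ndarray,
                      zone: DataZone) -> np.ndarray:
    """Lock the measured Fourier data: zone voxels come from ``original``.

    Both arrays are centered complex Fourier volumes; outside the zone the
    ``current`` (free, under-refinement) values pass through.
    """
    if current.shape != original.shape or current.shape != zone.membership.shape:
        raise ValueError("Fourier volume / zone grid mismatch")
    return np.where(zone.membership, original, current)


def run_round(initial_map: DensityMap, mask: Mask, zone: DataZone,
              n_iter: int,
              early_stop_tol: float | None = None,
              start_map: DensityMap | None = None
              ) -> tuple[DensityMap, np.ndarray]:
    """One restoration round: ``n_iter`` constraint cycles under a fixed mask.

    F₀ is computed once from ``initial_map`` and locked onto the data zone
    every cycle.  Iteration starts from ``start_map`` when given (used by
    later rounds to keep the wedge data restored so far) and from
    ``initial_map`` otherwise.  Returns the map after the final real-space
    constraint application and the per-iteration relative-change trace
    ``‖m_i − m_{i−1}‖/‖m_{i−1}‖``.  ``n_iter = 0`` returns the starting map
    unchanged.
    """
    start = initial_map if start_map is None else start_map
    if n_iter == 0:
        return start.copy(), np.empty(0)
    f0 = cfftn(initial_map.values)
    current = start.values.astype(complex)
    previous_real: np.ndarray | None = None
    trace = []
    for iteration in range(n_iter):
        constrained = apply_real_constraints(current, mask)
        spectrum = cfftn(constrained)
        spectrum = replace_data_zone(spectrum, f0, zone)
        current = icfftn(spectrum)
        if not np.all(np.isfinite(current)):
            raise FloatingPointError(
                f"non-finite values at iteration {iteration + 1}"
            )
        if previous_real is not None:
            denom = np.linalg.norm(previous_real)
            change = (np.linalg.norm(constrained - previous_real) / denom
                      if denom > 0 else 0.0)
            trace.append(change)
            if early_stop_tol is not None and change < early_stop_tol:
                previous_real = constrained
                break
        previous_real = constrained
    final = apply_real_constraints(current, mask)
    denom = np.linalg.norm(previous_real)
    trace.append(np.linalg.norm(final - previous_real) / denom
                 if denom > 0 else 0.0)
    result = DensityMap(final, initial_map.voxel_size,
                        label=f"{initial_map.label} restored")
    return result, np.asarray(trace)


def run_lottor(initial_map: DensityMap,
               params: LottorParams) -> RestorationResult:
    """Full multi-round restoration per the standard recipe.

    Round 1 masks from the initial map (or ``params.mask_override``); each
    later round regenerates the mask — same filter resolution and volume
    factor — from the previous round's output.
    """
    if not np.any(initial_map.values):
        raise ValueError("initial map is all zero")
    zone = make_data_zone(initial_map.box, params.tilt_max)
    if params.mask_override is not None:
        mask = params.mask_override
    else:
        mask = make_mask(initial_map, params, source="initial")
    per_round: list[DensityMap] = []
    traces: list[np.ndarray] = []
    masks: list[Mask] = [mask]
    current = initial_map
    for round_index in range(1, params.n_rounds + 1):
        if round_index > 1:
            mask = make_mask(current, params, source=f"round_{round_index - 1}")
            masks.append(mask)
        current, trace = run_round(
            initial_map, mask, zone, params.n_iter_per_round,
            params.early_stop_tol,
            start_map=None if round_index == 1 else current,
        )
        per_round.append(current)
        traces.append(trace)
        logger.info("round %d/%d: final relative change %.3g",
                    round_index, params.n_rounds,
                    trace[-1] if trace.size else float("nan"))
    return RestorationResult(per_round[-1], per_round, traces, params, masks)
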