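"""Chemical-shift displacement, tissue projection, masking and ROI statistics.

Slab-selective 13C imaging excites each metabolite at a slightly different
axial position because the slice-select gradient maps frequency to space: a
resonance offset ``df`` is displaced by ``dz = df / (gamma * Gss)``.  Tissue
probability maps derived from thin-slice 1H imaging therefore have to be
projected onto each metabolite's *displaced* slab before thresholding, and a
voxel only enters a tissue mask if it exceeds the threshold for all
metabolites simultaneously.

Conventions: voxel indices are 0-based; world z coordinates are metres from
the volume origin; a thin slice contributes to a slab when its centre lies in
the half-open displaced interval ``[lo, hi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

RATIO_COLUMNS = ["k_pl", "k_pb", "lac:pyr", "bic:pyr", "bic:lac"]


def chemical_shift_displacement(delta_f: float, gamma: float, gss: float) -> float:
    """Axial displacement (m) of a resonance offset under slab selection.

    Parameters
    ----------
    delta_f : float
        Frequency offset from the transmit centre (Hz).
    gamma : float
        Gyromagnetic ratio (Hz/T); must be positive.
    gss : float
        Slice-select gradient (T/m); must be nonzero.  The sign of the result
        carries the shift direction.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if gss == 0:
        raise ValueError("slice-select gradient must be nonzero")
    return delta_f / (gamma * gss)


@dataclass(frozen=True)
class TissueProbabilityVolume:
    """Per-tissue probability volumes on a thin axial slice grid.

    ``data`` maps tissue class name (e.g. ``gray``, ``white``, ``brain``) to a
    ``(nz, ny, nx)`` array of probabilities in [0, 1]; slice ``iz`` is centred
    at ``origin_z + (iz + 0.5) * thin_slice_thickness``.
    """

    data: Mapping[str, np.ndarray]
    thin_slice_thickness: float
    origin_z: float = 0.0

    def __post_init__(self):
        if self.thin_slice_thickness <= 0:
            raise ValueError("thin_slice_thickness must be > 0")
        shapes = {np.asarray(v).shape for v in self.data.values()}
        if len(shapes) != 1:
            raise ValueError("all tissue volumes must share one shape")
        for name, vol in self.data.items():
            vol = np.asarray(vol)
            if vol.ndim != 3:
                raise ValueError("tissue volumes must be 3-D (nz, ny, nx)")
            if np.any(vol < 0) or np.any(vol > 1):
                raise ValueError(f"probabilities for {name!r} outside [0, 1]")
        if "gray" in self.data and "white" in self.data:
            if np.any(np.asarray(self.data["gray"]) + np.asarray(self.data["white"]) > 1 + 1e-9):
                raise ValueError("gray + white probability exceeds 1")

    @property
    def n_slices(self) -> int:
        return next(iter(self.data.values())).shape[0]

    @property
    def slice_centers(self) -> np.ndarray:
        """World z coordinate of every thin slice centre (m)."""
        return self.origin_z + (np.arange(self.n_slices) + 0.5) * self.thin_slice_thickness


def project_probability(vol: TissueProbabilityVolume, slab_center: float,
                        slab_thickness: float, displacement: float = 0.0
                        ) -> Dict[str, np.ndarray]:
    """Mean tissue probability over the thin slices covered by a displaced slab.

    The slab interval is ``[slab_center + displacement - slab_thickness/2,
    slab_center + displacement + slab_thickness/2)``; thin slices count when
    their centre lies inside it.  Raises if the displaced slab covers no
    slices (entirely outside the volume).
    """
    if slab_thickness <= 0:
        raise ValueError("slab_thickness must be > 0")
    lo = slab_center + displacement - slab_thickness / 2
    hi = slab_center + displacement + slab_thickness / 2
    centers = vol.slice_centers
    inside = (centers >= lo) & (centers < hi)
    if not inside.any():
        raise ValueError(
            f"displaced slab [{lo:.4f}, {hi:.4f}) m lies outside the volume"
        )
    return {name: np.asarray(v)[inside].mean(axis=0) for name, v in vol.data.items()}


def metabolite_probability_maps(vol: TissueProbabilityVolume, slab_center: float,
                                slab_thickness: float,
                                displacements: Mapping[str, float]
                                ) -> Dict[str, Dict[str, np.ndarray]]:
    """Per-metabolite, per-tissue slab probability maps.

    ``displacements`` maps metabolite name to its chemical-shift displacement
    in metres; returns ``{metabolite: {tissue: 2-D map}}``.
    """
    return {
        met: project_probability(vol, slab_center, slab_thickness, dz)
        for met, dz in displacements.items()
    }


@dataclass(frozen=True)
class SlabMask:
    """Binary tissue masks for one imaging slab with their provenance.

    A voxel is included for a tissue class only when its probability exceeds
    the threshold (strict ``>``) in the displaced map of *every* metabolite.
    """

    data: Mapping[str, np.ndarray]
    threshold: float
    displacements: Mapping[str, float] = field(default_factory=dict)

    def __getitem__(self, tissue: str) -> np.ndarray:
        return self.data[tissue]


def make_binary_mask(per_metabolite_maps: Mapping[str, Mapping[str, np.ndarray]],
                     threshold: float = 0.60,
                     displacements: Mapping[str, float] | None = None) -> SlabMask:
    """Intersect per-metabolite probability maps into binary tissue masks.

    ``per_metabolite_maps`` is ``{metabolite: {tissue: 2-D probability map}}``
    as produced by :func:`metabolite_probability_maps`.  Inclusion requires
    probability strictly greater than ``threshold`` for all metabolites.
    """
    mets = list(per_metabolite_maps)
    if not mets:
        raise ValueError("no metabolite maps given")
    tissues = list(per_metabolite_maps[mets[0]])
    shape = np.asarray(per_metabolite_maps[mets[0]][tissues[0]]).shape
    masks = {}
    for tissue in tissues:
        mask = np.ones(shape, dtype=bool)
        for met in mets:
            pmap = np.asarray(per_metabolite_maps[met][tissue])
            if pmap.shape != shape:
                raise ValueError("probability map shapes do not match")
            mask &= pmap > threshold
        masks[tissue] = mask
    return SlabMask(data=masks, threshold=threshold,
                    displacements=dict(displacements or {}))


def summed_maps_and_normalize(dmi, brain_mask: np.ndarray) -> Dict[str, np.ndarray]:
    """Total metabolite maps normalised to peak brain pyruvate.

    Frames are summed in the complex domain, the magnitude is taken, and every
    map is divided by the maximum pyruvate value inside ``brain_mask`` so the
    peak pyruvate voxel maps to exactly 1.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    totals = {}
    for i, name in enumerate(dmi.basis.names):
        totals[name] = np.abs(dmi.data[i].sum(axis=0))
    peak = totals["pyruvate"][brain_mask].max()
    if peak <= 0:
        raise ValueError("peak pyruvate signal in the brain is zero")
    return {name: m / peak for name, m in totals.items()}


def ratio_maps(total_maps: Mapping[str, np.ndarray],
               mask: np.ndarray | None = None) -> Dict[str, np.ndarray]:
    """Lactate:pyruvate, bicarbonate:pyruvate and bicarbonate:lactate maps.

    Voxels with a non-positive denominator (or outside ``mask``) are invalid
    and carry NaN; they are excluded from all downstream summaries.
    """
    pyr = np.asarray(total_maps["pyruvate"], dtype=float)
    lac = np.asarray(total_maps["lactate"], dtype=float)
    bic = np.asarray(total_maps["bicarbonate"], dtype=float)
    valid = np.ones(pyr.shape, dtype=bool) if mask is None else np.asarray(mask, bool)

    def _ratio(num, den):
        ok = valid & (den > 0)
        out = np.full(num.shape, np.nan)
        out[ok] = num[ok] / den[ok]
        return out

    return {
        "lac:pyr": _ratio(lac, pyr),
        "bic:pyr": _ratio(bic, pyr),
        "bic:lac": _ratio(bic, lac),
    }


def roi_summary(value_maps: Mapping[str, np.ndarray] | Sequence[Mapping[str, np.ndarray]],
                roi_masks: Mapping[str, np.ndarray | Sequence[np.ndarray]]
                ) -> pd.DataFrame:
    """Mean and SD of quantitative maps over regions of interest.

    ``value_maps`` holds one quantity map (or a list of maps, one per dataset)
    per column name; columns are fixed to the standard report schema
    ``k_pl, k_pb, lac:pyr, bic:pyr, bic:lac``.  When lists are given, voxels
    are pooled across datasets before the mean/SD.  NaN voxels (invalid
    ratios) are excluded.  Returns a frame indexed by ``(roi, stat)`` with
    ``stat`` in ``{mean, sd}``.
    """
    if isinstance(value_maps, Mapping):
        value_maps = [value_maps]
    rows = {}
    for roi, masks in roi_masks.items():
        if isinstance(masks, np.ndarray):
            masks = [masks] * len(value_maps)
        if len(masks) != len(value_maps):
            raise ValueError("number of ROI masks does not match datasets")
        if not any(np.asarray(m, bool).any() for m in masks):
            raise ValueError(f"ROI {roi!r} is empty")
        means, sds = {}, {}
        for col in RATIO_COLUMNS:
            pooled = np.concatenate([
                np.asarray(vm[col], dtype=float)[np.asarray(m, bool)]
                for vm, m in zip(value_maps, masks)
            ])
            pooled = pooled[np.isfinite(pooled)]
            means[col] = pooled.mean() if pooled.size else np.nan
            sds[col] = pooled.std(ddof=0) if pooled.size else np.nan
        rows[(roi, "mean")] = means
        rows[(roi, "sd")] = sds
    out = pd.DataFrame.from_dict(rows, orient="index")[RATIO_COLUMNS]
    out.index = pd.MultiIndex.from_tuples(out.index, names=["roi", "stat"])
    return out


@dataclass(frozen=True)
class PairedComparison:
    """Result of a paired gray-vs-white comparison."""

    statistic: float
    p_value: float
    p_adjusted: float
    n_pairs: int
    significant: bool
    degenerate: bool = False


def compare_gray_white(gray_values: np.ndarray, white_values: np.ndarray,
                       n_comparisons: int = 1, alpha: float = 0.05
                       ) -> PairedComparison:
    """Wilcoxon signed-rank test on paired slice-wise values, Bonferroni adjusted.

    The exact null distribution is used for up to 25 pairs (when differences
    are free of zeros and ties), the normal approximation above that.  The
    adjusted p-value is ``min(1, p * n_comparisons)``; all-zero differences
    are degenerate and reported as ``p = 1``.
    """
    gray = np.asarray(gray_values, dtype=float)
    white = np.asarray(white_values, dtype=float)
    if gray.shape != white.shape:
        raise ValueError("paired samples must have equal length")
    if gray.ndim != 1 or gray.size < 1:
        raise ValueError("paired samples must be non-empty 1-D vectors")
    diffs = gray - white
    if np.all(diffs == 0):
        return PairedComparison(statistic=0.0, p_value=1.0, p_adjusted=1.0,
                                n_pairs=gray.size, significant=False,
                                degenerate=True)
    has_ties = len(np.unique(np.abs(diffs[diffs != 0]))) < np.count_nonzero(diffs)
    exact_ok = gray.size <= 25 and not np.any(diffs == 0) and not has_ties
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(gray, white, method=method)
    p_adj = min(1.0, float(res.pvalue) * n_comparisons)
    return PairedComparison(statistic=float(res.statistic),
                            p_value=float(res.pvalue), p_adjusted=p_adj,
                            n_pairs=gray.size, significant=p_adj < alpha)
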