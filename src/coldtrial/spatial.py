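"""Paired pre-/on-treatment statistics on phenotyped cell maps.

Inputs are per-sample tables of cell centroids (micrometres) with binary
phenotype flags, plus the analysed region area in mm².  The module
computes cell densities, radius-based colocalization fractions (closed
ball, boundary inclusive), marker-positive fractions, and exact paired
Wilcoxon signed-rank tests across patients.

Edge effects at region borders are deliberately not corrected; raw
fractions are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .design import ValidationError

__all__ = [
    "PHENOTYPE_FLAGS",
    "CellMap",
    "ColocalizationResult",
    "MarkerFraction",
    "WilcoxonResult",
    "PairedDensityResult",
    "PanelResult",
    "cell_density",
    "colocalization_fraction",
    "marker_positive_fraction",
    "paired_wilcoxon",
    "paired_panel_analysis",
]

PHENOTYPE_FLAGS = ("CD8", "CD4", "CD20", "CD163", "CD3", "PD1", "CD23")
TIMEPOINTS = ("baseline", "C2D1")


@dataclass
class CellMap:
    """Phenotyped cells of one sample (µm coordinates, area in mm²).

    ``cells`` holds columns ``x_um``, ``y_um`` and one boolean column per
    phenotype flag.  The CD3 flag must cover every CD4+ or CD8+ cell.
    """

    sample_id: str
    patient_id: str
    timepoint: str
    area_mm2: float
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"timepoint must be one of {TIMEPOINTS}, got {self.timepoint!r}"
            )
        if not (self.area_mm2 > 0 and math.isfinite(self.area_mm2)):
            raise ValidationError(f"area_mm2 must be positive, got {self.area_mm2}")
        for col in ("x_um", "y_um"):
            if col not in self.cells.columns:
                raise ValidationError(f"cells table lacks column {col!r}")
            if len(self.cells) and not np.isfinite(self.cells[col].to_numpy(float)).all():
                raise ValidationError(f"non-finite coordinates in {col!r}")
        for flag in self.flags:
            self.cells[flag] = self.cells[flag].astype(bool)
        if "CD3" in self.cells.columns:
            for sub in ("CD4", "CD8"):
                if sub in self.cells.columns:
                    bad = self.cells[sub] & ~self.cells["CD3"]
                    if bad.any():
                        raise ValidationError(
                            f"{int(bad.sum())} {sub}+ cells lack the CD3 flag "
                            f"in sample {self.sample_id}"
                        )

    @property
    def flags(self) -> list[str]:
        return [c for c in self.cells.columns if c in PHENOTYPE_FLAGS]

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def coords(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(float)

    def mask(self, phenotype: str) -> np.ndarray:
        if phenotype not in self.flags:
            raise ValidationError(
                f"unknown phenotype {phenotype!r}; sample {self.sample_id} "
                f"carries {self.flags}"
            )
        return self.cells[phenotype].to_numpy(bool)


def cell_density(cmap: CellMap, phenotype: str) -> float:
    """Cells carrying ``phenotype`` per mm² of analysed region."""
    return float(cmap.mask(phenotype).sum()) / cmap.area_mm2


@dataclass(frozen=True)
class ColocalizationResult:
    sample_id: str
    radius_um: float
    n_source: int
    n_colocalized: int
    fraction: float
    empty_source: bool = False


def colocalization_fraction(
    cmap: CellMap,
    source: str = "CD20",
    targets: Sequence[str] = ("CD4", "CD8"),
    radius_um: float = 10.0,
) -> ColocalizationResult:
    """Fraction of source-phenotype cells with at least one
    target-phenotype cell within ``radius_um`` (Euclidean, inclusive).

    A cell carrying both source and a target flag never counts as its
    own neighbour: colocalization means proximity to a distinct cell.
    """
    if radius_um <= 0:
        raise ValidationError(f"radius must be > 0, got {radius_um}")
    src_idx = np.flatnonzero(cmap.mask(source))
    tgt_mask = np.zeros(cmap.n_cells, dtype=bool)
    for t in targets:
        tgt_mask |= cmap.mask(t)
    tgt_idx = np.flatnonzero(tgt_mask)
    if len(src_idx) == 0:
        return ColocalizationResult(
            cmap.sample_id, radius_um, 0, 0, 0.0, empty_source=True
        )
    if len(tgt_idx) == 0:
        return ColocalizationResult(cmap.sample_id, radius_um, len(src_idx), 0, 0.0)
    xy = cmap.coords()
    tree = cKDTree(xy[tgt_idx])
    hits = tree.query_ball_point(xy[src_idx], r=radius_um)
    n_coloc = 0
    for i, neigh in zip(src_idx, hits):
        # drop self-match (same cell index), then any neighbour counts
        if any(tgt_idx[j] != i for j in neigh):
            n_coloc += 1
    return ColocalizationResult(
        sample_id=cmap.sample_id,
        radius_um=radius_um,
        n_source=len(src_idx),
        n_colocalized=n_coloc,
        fraction=n_coloc / len(src_idx),
    )


def colocalized_source_indices(
    cmap: CellMap,
    source: str,
    targets: Sequence[str],
    radius_um: float,
) -> set[int]:
    """Indices (row positions) of colocalized source cells — used by the
    brute-force equivalence tests."""
    src_idx = np.flatnonzero(cmap.mask(source))
    tgt_mask = np.zeros(cmap.n_cells, dtype=bool)
    for t in targets:
        tgt_mask |= cmap.mask(t)
    tgt_idx = np.flatnonzero(tgt_mask)
    if len(src_idx) == 0 or len(tgt_idx) == 0:
        return set()
    xy = cmap.coords()
    tree = cKDTree(xy[tgt_idx])
    hits = tree.query_ball_point(xy[src_idx], r=radius_um)
    return {
        int(i)
        for i, neigh in zip(src_idx, hits)
        if any(tgt_idx[j] != i for j in neigh)
    }


@dataclass(frozen=True)
class MarkerFraction:
    fraction: float
    n_base: int
    n_positive: int
    empty_denominator: bool = False


def marker_positive_fraction(
    cmap: CellMap, base: str, marker: str = "PD1"
) -> MarkerFraction:
    """Fraction of ``base``-flagged cells that also carry ``marker``."""
    base_mask = cmap.mask(base)
    n_base = int(base_mask.sum())
    if n_base == 0:
        return MarkerFraction(0.0, 0, 0, empty_denominator=True)
    n_pos = int((base_mask & cmap.mask(marker)).sum())
    return MarkerFraction(n_pos / n_base, n_base, n_pos)


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

EXACT_N_MAX = 25


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # min(W+, W-) on the non-zero differences
    w_plus: float
    p_value: float
    n_pairs: int
    n_used: int  # pairs remaining after zero handling
    method: str  # "exact" or "normal"
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating all sign assignments.

    Works on doubled ranks so midranks from ties stay integral; the
    distribution of W+ is built by dynamic programming (subset-sum
    polynomial), equivalent to summing over all 2^n sign vectors.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def paired_wilcoxon(
    pre: Sequence[float],
    post: Sequence[float],
    zero_method: str = "wilcox",
    mode: str = "auto",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped before ranking (``wilcox`` convention)
    or kept in the ranking and split between the sums (``pratt``).  The
    null distribution is exact by enumeration for up to 25 informative
    pairs, and a normal approximation with tie correction and continuity
    correction beyond that; ``mode`` may force ``"exact"`` or
    ``"normal"``.
    """
    pre_arr = np.asarray(pre, dtype=float)
    post_arr = np.asarray(post, dtype=float)
    if pre_arr.shape != post_arr.shape or pre_arr.ndim != 1:
        raise ValidationError("pre and post must be 1-d sequences of equal length")
    if len(pre_arr) < 1:
        raise ValidationError("need at least one pair")
    if zero_method not in ("wilcox", "pratt"):
        raise ValidationError(f"unknown zero_method {zero_method!r}")
    d = post_arr - pre_arr
    n_pairs = len(d)

    if zero_method == "wilcox":
        d_used = d[d != 0]
        ranks_all = stats.rankdata(np.abs(d_used)) if len(d_used) else np.array([])
        pos_ranks = ranks_all[d_used > 0] if len(d_used) else np.array([])
        ranks_for_null = ranks_all
    else:  # pratt: rank zeros too, then discard their ranks from both sums
        ranks_all = stats.rankdata(np.abs(d))
        d_used = d[d != 0]
        pos_ranks = ranks_all[d > 0]
        ranks_for_null = ranks_all[d != 0]

    n_used = len(d_used)
    if n_used == 0:
        return WilcoxonResult(
            statistic=0.0,
            w_plus=0.0,
            p_value=1.0,
            n_pairs=n_pairs,
            n_used=0,
            method="degenerate",
            degenerate=True,
        )
    w_plus = float(pos_ranks.sum())
    w_minus = float(ranks_for_null.sum()) - w_plus
    stat = min(w_plus, w_minus)

    use_exact = mode == "exact" or (mode == "auto" and n_used <= EXACT_N_MAX)
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    if use_exact:
        p = _exact_signed_rank_p(ranks_for_null, w_plus)
        method = "exact"
    else:
        r = ranks_for_null
        mean = float(r.sum()) / 2.0
        var = float(np.sum(r ** 2)) / 4.0  # tie-corrected: sum of rank^2 / 4
        if var == 0:
            p = 1.0
        else:
            z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
            p = min(1.0, p)
        method = "normal"
    return WilcoxonResult(
        statistic=stat,
        w_plus=w_plus,
        p_value=p,
        n_pairs=n_pairs,
        n_used=n_used,
        method=method,
    )


# ---------------------------------------------------------------------------
# paired panel across patients
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedDensityResult:
    phenotype: str
    densities_pre: tuple[float, ...]
    densities_post: tuple[float, ...]
    patient_ids: tuple[str, ...]
    n_pairs: int
    n_increased: int
    wilcoxon_statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class PanelResult:
    densities: dict[str, PairedDensityResult]
    colocalization: dict[str, ColocalizationResult]  # per sample_id
    colocalization_delta: dict[str, float]  # per patient, post - pre
    colocalization_test: Optional[WilcoxonResult]


def _pair_maps(maps: Sequence[CellMap]) -> list[tuple[str, CellMap, CellMap]]:
    by_patient: dict[str, dict[str, CellMap]] = {}
    for m in maps:
        slot = by_patient.setdefault(m.patient_id, {})
        if m.timepoint in slot:
            raise ValidationError(
                f"patient {m.patient_id} has duplicate {m.timepoint} maps"
            )
        slot[m.timepoint] = m
    pairs = []
    for pid in sorted(by_patient):
        slot = by_patient[pid]
        if set(slot) != set(TIMEPOINTS):
            raise ValidationError(
                f"patient {pid} lacks a complete baseline/C2D1 pair "
                f"(has {sorted(slot)})"
            )
        pairs.append((pid, slot["baseline"], slot["C2D1"]))
    return pairs


def paired_panel_analysis(
    maps: Sequence[CellMap],
    phenotypes: Sequence[str] = ("CD8", "CD4", "CD20", "CD163"),
    coloc_source: str = "CD20",
    coloc_targets: Sequence[str] = ("CD4", "CD8"),
    radius_um: float = 10.0,
) -> PanelResult:
    """Per-phenotype paired density comparison plus colocalization deltas
    across a set of baseline/on-treatment map pairs (one pair per
    patient, validated)."""
    pairs = _pair_maps(maps)
    densities: dict[str, PairedDensityResult] = {}
    for ph in phenotypes:
        pre = [cell_density(m_pre, ph) for _, m_pre, _ in pairs]
        post = [cell_density(m_post, ph) for _, _, m_post in pairs]
        wr = paired_wilcoxon(pre, post)
        densities[ph] = PairedDensityResult(
            phenotype=ph,
            densities_pre=tuple(pre),
            densities_post=tuple(post),
            patient_ids=tuple(pid for pid, _, _ in pairs),
            n_pairs=len(pairs),
            n_increased=sum(1 for a, b in zip(pre, post) if b > a),
            wilcoxon_statistic=wr.statistic,
            p_value=wr.p_value,
            degenerate=wr.degenerate,
        )
    coloc: dict[str, ColocalizationResult] = {}
    deltas: dict[str, float] = {}
    pre_fracs, post_fracs = [], []
    for pid, m_pre, m_post in pairs:
        c_pre = colocalization_fraction(m_pre, coloc_source, coloc_targets, radius_um)
        c_post = colocalization_fraction(m_post, coloc_source, coloc_targets, radius_um)
        coloc[m_pre.sample_id] = c_pre
        coloc[m_post.sample_id] = c_post
        deltas[pid] = c_post.fraction - c_pre.fraction
        pre_fracs.append(c_pre.fraction)
        post_fracs.append(c_post.fraction)
    coloc_test = paired_wilcoxon(pre_fracs, post_fracs) if pairs else None
    return PanelResult(
        densities=densities,
        colocalization=coloc,
        colocalization_delta=deltas,
        colocalization_test=coloc_test,
    )
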