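"""Synthetic trial cohorts and paired cell maps.

Generators reproduce the statistical structure the analysis code
assumes so every pipeline stage can run, and be tested against known
truth, without external data.  Survival times are exponential (one
parameter pins the median exactly); overall survival is constructed as
PFS plus an independent residual whose rate is calibrated numerically so
the OS median matches, which also guarantees OS >= PFS patient by
patient.  Spatial maps default to homogeneous Poisson with an optional
Thomas cluster process to stress the neighbour search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .design import ValidationError
from .spatial import CellMap, PHENOTYPE_FLAGS

__all__ = [
    "CohortScenario",
    "SpatialScenario",
    "generate_cohort",
    "generate_cell_maps",
    "cell_maps_to_frames",
    "cell_maps_from_frames",
    "paper_like_scenario",
]

LN2 = math.log(2.0)

# cosmetic histology mix for realistic-looking fixtures; unused by statistics
HISTOLOGY_MIX = (("leiomyosarcoma", 0.45), ("synovial sarcoma", 0.18), ("other", 0.37))


@dataclass(frozen=True)
class CohortScenario:
    """Parameters of a synthetic single-arm cohort."""

    n_patients: int = 50
    true_orr: float = 0.10
    accrual_rate: float = 2.0  # patients per month
    pfs_median_months: float = 1.8
    os_median_months: float = 15.1
    dor_median_months: float = 7.8
    prior_pfs_lognormal_params: tuple[float, float] = (1.2, 0.8)
    censor_admin_months: float = 36.0
    weibull_shape: float = 1.0  # 1 = exponential
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be >= 1")
        if not (0 <= self.true_orr <= 1):
            raise ValidationError("true_orr must lie in [0, 1]")
        for name in (
            "pfs_median_months",
            "os_median_months",
            "dor_median_months",
            "censor_admin_months",
            "accrual_rate",
            "weibull_shape",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.os_median_months <= self.pfs_median_months:
            raise ValidationError(
                "os_median_months must exceed pfs_median_months "
                f"({self.os_median_months} <= {self.pfs_median_months})"
            )


@dataclass(frozen=True)
class SpatialScenario:
    """Parameters of paired baseline/on-treatment cell maps."""

    n_pairs: int = 7
    area_mm2: float = 1.0
    baseline_density_per_mm2: dict[str, float] = field(
        default_factory=lambda: {"CD8": 150.0, "CD4": 200.0, "CD20": 80.0, "CD163": 120.0}
    )
    post_fold_change: dict[str, float] = field(
        default_factory=lambda: {"CD8": 2.0, "CD4": 1.5, "CD20": 1.8, "CD163": 1.4}
    )
    clustering: float = 0.0  # Thomas parent intensity per mm²; 0 = Poisson
    cluster_sigma_um: float = 25.0
    pd1_fraction_pre: float = 0.15
    pd1_fraction_post: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.area_mm2 <= 0:
            raise ValidationError("area_mm2 must be > 0")
        if any(v < 0 for v in self.baseline_density_per_mm2.values()):
            raise ValidationError("densities must be >= 0")
        if any(v <= 0 for v in self.post_fold_change.values()):
            raise ValidationError("fold changes must be > 0")
        if self.clustering < 0:
            raise ValidationError("clustering must be >= 0")
        for name in ("pd1_fraction_pre", "pd1_fraction_post"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValidationError(f"{name} must lie in [0, 1]")


def paper_like_scenario(seed: int = 0) -> tuple[CohortScenario, SpatialScenario]:
    """Presets emulating the reported cohort: ~50 patients, true ORR near
    10%, median PFS 1.8 / OS 15.1 / DOR 7.8 months, and 7 biopsy pairs
    with treatment-shifted immune densities."""
    return CohortScenario(seed=seed), SpatialScenario(seed=seed)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _os_residual_rate(pfs_median: float, os_median: float) -> float:
    """Rate of the exponential residual R such that the median of
    PFS + R equals ``os_median`` when PFS is exponential with median
    ``pfs_median``.  Uses the hypoexponential CDF and a bracketed root
    solve."""
    lam1 = LN2 / pfs_median

    def median_gap(lam2: float) -> float:
        if abs(lam2 - lam1) < 1e-10:
            lam2 = lam1 * (1 + 1e-8)
        t = os_median
        cdf = 1.0 - (
            lam2 * math.exp(-lam1 * t) - lam1 * math.exp(-lam2 * t)
        ) / (lam2 - lam1)
        return cdf - 0.5

    # residual median is below os_median and above ~os_median - pfs stuff
    lo, hi = 1e-6, LN2 / max(os_median - pfs_median, 1e-6) * 50
    return float(optimize.brentq(median_gap, lo, hi))


def _draw_survival(rng: np.random.Generator, n: int, median: float, shape: float) -> np.ndarray:
    """Weibull draws with the given median; shape 1 reduces to
    exponential."""
    scale = median / (LN2 ** (1.0 / shape))
    return scale * rng.weibull(shape, size=n)


def generate_cohort(scenario: CohortScenario) -> pd.DataFrame:
    """Generate a patient-level table in the analysis CSV schema.

    Columns: patient_id, histology, evaluable_efficacy, bor,
    response_onset_months, pfs_months, pfs_event, os_months, os_event,
    prior_pfs_months.  Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_patients

    responder = rng.random(n) < scenario.true_orr
    pfs = _draw_survival(rng, n, scenario.pfs_median_months, scenario.weibull_shape)

    # responders: response onset near the first tumour assessment, then
    # progression at onset + duration-of-response
    onset = rng.uniform(1.6, 3.2, size=n)
    dor = _draw_survival(rng, n, scenario.dor_median_months, 1.0)
    pfs = np.where(responder, onset + dor, pfs)

    res_rate = _os_residual_rate(scenario.pfs_median_months, scenario.os_median_months)
    os_t = pfs + rng.exponential(1.0 / res_rate, size=n)

    accrual = np.sort(rng.uniform(0, n / scenario.accrual_rate, size=n))
    follow_up = np.maximum(scenario.censor_admin_months - accrual, 0.01)

    pfs_event = pfs <= follow_up
    pfs_obs = np.minimum(pfs, follow_up)
    os_event = os_t <= follow_up
    os_obs = np.minimum(os_t, follow_up)

    prior_mu, prior_sigma = scenario.prior_pfs_lognormal_params
    prior_pfs = rng.lognormal(prior_mu, prior_sigma, size=n)

    hist_labels = [h for h, _ in HISTOLOGY_MIX]
    hist_p = np.array([p for _, p in HISTOLOGY_MIX])
    histology = rng.choice(hist_labels, size=n, p=hist_p / hist_p.sum())

    bor = np.where(responder, "PR", np.where(rng.random(n) < 0.45, "SD", "PD"))

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "histology": histology,
            "evaluable_efficacy": 1,
            "bor": bor,
            "response_onset_months": np.where(responder, np.round(onset, 6), np.nan),
            "pfs_months": np.round(pfs_obs, 6),
            "pfs_event": pfs_event.astype(int),
            "os_months": np.round(os_obs, 6),
            "os_event": os_event.astype(int),
            "prior_pfs_months": np.round(prior_pfs, 6),
        }
    )
    return df


# ---------------------------------------------------------------------------
# cell-map generation
# ---------------------------------------------------------------------------


def _draw_points(
    rng: np.random.Generator,
    density_per_mm2: float,
    area_mm2: float,
    clustering: float,
    cluster_sigma_um: float,
) -> np.ndarray:
    """Point locations (µm) in a square region of the given area.

    Homogeneous Poisson by default; with ``clustering`` > 0, a Thomas
    process with that parent intensity per mm² and Gaussian offspring
    displacement."""
    side_um = math.sqrt(area_mm2) * 1000.0
    n_expected = density_per_mm2 * area_mm2
    if n_expected <= 0:
        return np.empty((0, 2))
    if clustering <= 0:
        n = rng.poisson(n_expected)
        return rng.uniform(0, side_um, size=(n, 2))
    n_parents = max(1, rng.poisson(clustering * area_mm2))
    parents = rng.uniform(0, side_um, size=(n_parents, 2))
    mean_offspring = n_expected / n_parents
    pts = []
    for p in parents:
        k = rng.poisson(mean_offspring)
        if k:
            pts.append(p + rng.normal(0, cluster_sigma_um, size=(k, 2)))
    if not pts:
        return np.empty((0, 2))
    xy = np.vstack(pts)
    return np.clip(xy, 0, side_um)  # keep offspring inside the region


def _make_map(
    rng: np.random.Generator,
    sample_id: str,
    patient_id: str,
    timepoint: str,
    scenario: SpatialScenario,
) -> CellMap:
    rows = []
    pd1_frac = (
        scenario.pd1_fraction_pre if timepoint == "baseline" else scenario.pd1_fraction_post
    )
    for ph in sorted(scenario.baseline_density_per_mm2):
        rate = scenario.baseline_density_per_mm2[ph] * (
            scenario.post_fold_change.get(ph, 1.0) if timepoint == "C2D1" else 1.0
        )
        xy = _draw_points(
            rng, rate, scenario.area_mm2, scenario.clustering, scenario.cluster_sigma_um
        )
        for x, y in xy:
            flags = {f: False for f in PHENOTYPE_FLAGS}
            flags[ph] = True
            if ph in ("CD4", "CD8"):
                flags["CD3"] = True
                flags["PD1"] = bool(rng.random() < pd1_frac)
            rows.append({"x_um": round(float(x), 4), "y_um": round(float(y), 4), **flags})
    cols = ["x_um", "y_um", *PHENOTYPE_FLAGS]
    cells = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(
        {c: pd.Series(dtype=(bool if c in PHENOTYPE_FLAGS else float)) for c in cols}
    )
    return CellMap(
        sample_id=sample_id,
        patient_id=patient_id,
        timepoint=timepoint,
        area_mm2=scenario.area_mm2,
        cells=cells,
    )


def generate_cell_maps(scenario: SpatialScenario) -> list[CellMap]:
    """Paired baseline/C2D1 maps for ``n_pairs`` patients.

    Baseline densities follow the configured rates; on-treatment rates
    are multiplied by the per-phenotype fold change.  PD-1 flags are
    assigned to T cells at the configured timepoint-specific fractions;
    the CD3 flag covers every CD4+/CD8+ cell by construction.
    """
    rng = np.random.default_rng(scenario.seed)
    maps: list[CellMap] = []
    for i in range(scenario.n_pairs):
        pid = f"BX{i + 1:02d}"
        maps.append(_make_map(rng, f"{pid}-B", pid, "baseline", scenario))
        maps.append(_make_map(rng, f"{pid}-C2D1", pid, "C2D1", scenario))
    return maps


def cell_maps_to_frames(maps: Sequence[CellMap]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten maps into the cells/samples CSV schema pair."""
    cell_rows = []
    sample_rows = []
    for m in maps:
        sample_rows.append(
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "timepoint": m.timepoint,
                "area_mm2": m.area_mm2,
            }
        )
        for _, row in m.cells.iterrows():
            rec = {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "timepoint": m.timepoint,
                "x_um": row["x_um"],
                "y_um": row["y_um"],
            }
            for f in PHENOTYPE_FLAGS:
                rec[f] = int(bool(row[f])) if f in m.cells.columns else 0
            cell_rows.append(rec)
    cells = pd.DataFrame(
        cell_rows,
        columns=["sample_id", "patient_id", "timepoint", "x_um", "y_um", *PHENOTYPE_FLAGS],
    )
    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "patient_id", "timepoint", "area_mm2"]
    )
    return cells, samples


def cell_maps_from_frames(
    cells: pd.DataFrame, samples: pd.DataFrame
) -> list[CellMap]:
    """Rebuild CellMap objects from the cells/samples schema."""
    maps = []
    for _, s in samples.iterrows():
        sub = cells[cells["sample_id"] == s["sample_id"]]
        flag_cols = [c for c in sub.columns if c in PHENOTYPE_FLAGS]
        table = sub[["x_um", "y_um", *flag_cols]].reset_index(drop=True).copy()
        for c in flag_cols:
            table[c] = table[c].astype(int).astype(bool)
        maps.append(
            CellMap(
                sample_id=str(s["sample_id"]),
                patient_id=str(s["patient_id"]),
                timepoint=str(s["timepoint"]),
                area_mm2=float(s["area_mm2"]),
                cells=table,
            )
        )
    return maps
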