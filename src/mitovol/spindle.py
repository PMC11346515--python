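"""Landmark-based spindle geometry and the statistical comparisons.

Distances follow the standard mitotic-spindle definitions: P2P between
the two centrosomes, sK2K between sister kinetochores, sT2T between
corresponding sister telomeres (same arm), and K2P from a kinetochore to
its nearer pole.  Cells are staged ordinally by centrosome separation
(ATU, arbitrary time units), the stand-in for elapsed mitotic time when
only fixed cells are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volio import read_landmarks

LARGE_CHROMOSOMES = {"chr1", "chr2", "chr3", "chr4", "chr5"}
SMALL_CHROMOSOMES = {"chr19", "chr20", "chr21", "chr22"}


@dataclass
class LandmarkSet:
    """Centrosome/kinetochore/telomere coordinates (nm) with pairing metadata."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"kind", "x_nm", "y_nm", "z_nm"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"landmark set missing columns: {sorted(missing)}")

    @classmethod
    def from_csv(cls, path) -> "LandmarkSet":
        return cls(read_landmarks(path))

    def positions(self, mask=None) -> np.ndarray:
        sub = self.table if mask is None else self.table[mask]
        return sub[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)

    @property
    def centrosomes(self) -> np.ndarray:
        return self.positions(self.table["kind"] == "centrosome")


@dataclass
class StageCall:
    cell_id: str
    p2p_um: float | None
    scatter_um: float | None
    stage: str
    atu: int | None


def pairwise_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points given in nm, returned in µm."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("landmark coordinates must be finite")
    return float(np.linalg.norm(a - b) / 1e3)


def p2p_distance(landmarks: LandmarkSet) -> float:
    poles = landmarks.centrosomes
    if len(poles) != 2:
        raise ValueError(f"P2P needs exactly 2 centrosomes, found {len(poles)}")
    return pairwise_distance(poles[0], poles[1])


def spindle_summary(landmarks: LandmarkSet) -> pd.DataFrame:
    """Per-chromosome spindle distances (µm): sK2K, sT2T per arm, K2P per sister.

    Kinetochores are paired across sisters by ``chromosome_id``; telomeres
    additionally by ``arm`` (p with p, q with q).  K2P uses the nearer
    centrosome, since sister kinetochores face opposite poles.  Unpaired
    kinetochores are excluded with a notice row left out of the table.
    """
    table = landmarks.table
    poles = landmarks.centrosomes
    rows = []
    kts = table[table["kind"] == "kinetochore"]
    tels = table[table["kind"] == "telomere"]
    for chrom, group in kts.groupby("chromosome_id"):
        if len(group) != 2:
            import logging

            logging.getLogger(__name__).info(
                "chromosome %s: %d kinetochores, expected a sister pair; excluded", chrom, len(group)
            )
            continue
        ka, kb = group[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        row = {"chromosome_id": chrom, "sk2k_um": pairwise_distance(ka, kb)}
        if len(poles) == 2:
            row["k2p_a_um"] = min(pairwise_distance(ka, p) for p in poles)
            row["k2p_b_um"] = min(pairwise_distance(kb, p) for p in poles)
        chrom_tels = tels[tels["chromosome_id"] == chrom]
        for arm in ("p", "q"):
            pair = chrom_tels[chrom_tels["arm"] == arm]
            if len(pair) == 2:
                ta, tb = pair[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
                row[f"st2t_{arm}_um"] = pairwise_distance(ta, tb)
        rows.append(row)
    return pd.DataFrame(rows)


def group_contrast(summary: pd.DataFrame, column: str) -> dict:
    """Mean ± sd of one distance column for large (Chr1-5) vs small (Chr19-22)."""
    large = summary[summary["chromosome_id"].isin(LARGE_CHROMOSOMES)][column].dropna()
    small = summary[summary["chromosome_id"].isin(SMALL_CHROMOSOMES)][column].dropna()
    return {
        "large_mean": float(large.mean()) if len(large) else None,
        "large_sd": float(large.std(ddof=1)) if len(large) > 1 else None,
        "small_mean": float(small.mean()) if len(small) else None,
        "small_sd": float(small.std(ddof=1)) if len(small) > 1 else None,
    }


def chromosome_scatter(landmarks: LandmarkSet) -> float | None:
    """Spread of chromosome centroids along the pole axis (µm, sd).

    This formalizes "extent of chromosome scattering" as the standard
    deviation of per-chromosome landmark centroids projected on the
    pole-to-pole axis; it is this package's own definition.
    """
    poles = landmarks.centrosomes
    if len(poles) != 2:
        return None
    axis = poles[1] - poles[0]
    norm = np.linalg.norm(axis)
    if norm == 0:
        return None
    axis = axis / norm
    chrom_rows = landmarks.table[landmarks.table["kind"] != "centrosome"]
    if "chromosome_id" not in chrom_rows.columns or chrom_rows.empty:
        return None
    centroids = chrom_rows.groupby("chromosome_id")[["x_nm", "y_nm", "z_nm"]].mean().to_numpy()
    if len(centroids) < 2:
        return None
    proj = centroids @ axis
    return float(np.std(proj, ddof=1) / 1e3)


def stage_cells(
    cells: Sequence[tuple[str, LandmarkSet, bool]],
    anaphase_sk2k_um: float = 2.0,
    early_prometaphase_p2p_um: float = 10.0,
    metaphase_p2p_um: float = 13.0,
) -> list[StageCall]:
    """Order fixed cells along mitosis by centrosome separation.

    Each cell is ``(cell_id, landmarks, envelope_flag)``.  Nuclear-envelope
    deposition defines telophase; a mean sister-kinetochore separation
    above ``anaphase_sk2k_um`` defines anaphase; remaining cells are
    prometaphase/metaphase-like, split by P2P.  Within the pre-anaphase
    and anaphase cohorts, cells are ranked by increasing P2P, and the ATU
    index concatenates the cohorts (pre-anaphase, anaphase, telophase).
    """
    calls = []
    for cell_id, landmarks, envelope in cells:
        try:
            p2p = p2p_distance(landmarks)
        except ValueError:
            calls.append(StageCall(cell_id, None, None, "unknown", None))
            continue
        scatter = chromosome_scatter(landmarks)
        if envelope:
            stage = "telophase"
        else:
            summary = spindle_summary(landmarks)
            mean_sk2k = summary["sk2k_um"].mean() if "sk2k_um" in summary and len(summary) else 0.0
            if mean_sk2k and mean_sk2k > anaphase_sk2k_um:
                stage = "anaphase"
            elif p2p < early_prometaphase_p2p_um:
                stage = "early-prometaphase"
            elif p2p < metaphase_p2p_um:
                stage = "late-prometaphase"
            else:
                stage = "metaphase-like"
        calls.append(StageCall(cell_id, p2p, scatter, stage, None))

    cohort_rank = {
        "early-prometaphase": 0,
        "late-prometaphase": 0,
        "metaphase-like": 0,
        "anaphase": 1,
        "telophase": 2,
        "unknown": 3,
    }
    staged = [c for c in calls if c.stage != "unknown"]
    staged.sort(key=lambda c: (cohort_rank[c.stage], c.p2p_um))
    for atu, call in enumerate(staged, start=1):
        call.atu = atu
    return calls


# ---------------------------------------------------------------------------
# statistics


@dataclass
class GroupComparison:
    shapiro_p_a: float
    shapiro_p_b: float
    t_statistic: float
    p_value: float


def compare_groups(samples_a, samples_b, equal_var: bool = True) -> GroupComparison:
    """Shapiro-Wilk normality per group + two-tailed Student's t test.

    The t test pools variances by default (Welch available via
    ``equal_var=False``).  All statistics are returned; no significance
    thresholding is applied.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance; t test undefined")
    sw_a = stats.shapiro(a).pvalue
    sw_b = stats.shapiro(b).pvalue
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(float(sw_a), float(sw_b), float(t), float(p))


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f_statistic: float
    p_value: float


def regress_and_anova(x, y) -> RegressionResult:
    """Ordinary least squares with intercept + ANOVA F test for the slope.

    Exact closed forms; a perfect (collinear) fit reports the smallest
    positive float as the p-value floor rather than zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired observations")
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0:
        raise ValueError("x must not be constant")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    fitted = intercept + slope * x
    ss_reg = float(np.sum((fitted - y.mean()) ** 2))
    ss_res = float(np.sum((y - fitted) ** 2))
    df_res = len(x) - 2
    if ss_res <= 0:
        return RegressionResult(slope, intercept, float("inf"), float(np.finfo(float).tiny))
    f = ss_reg / (ss_res / df_res)
    p = float(stats.f.sf(f, 1, df_res))
    return RegressionResult(slope, intercept, float(f), max(p, float(np.finfo(float).tiny)))


def t_test_power(delta: float, sd: float, n_a: int, n_b: int, alpha: float = 0.05) -> float:
    """Closed-form power of the pooled two-sample t test (noncentral t)."""
    df = n_a + n_b - 2
    ncp = (delta / sd) * np.sqrt(n_a * n_b / (n_a + n_b))
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
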