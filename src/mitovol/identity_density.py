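"""Chromosome identification and the densitometry chain.

From per-object geometry plus known DNA contents this module derives the
linear packing ratio (Mb/µm), the volumetric DNA density (Mb/µm³), and —
assuming a 195 bp nucleosome repeat — the nucleosome number density,
the volume available per nucleosome, the molar nucleosome concentration,
and the chromatin volume concentration (CVC).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

AVOGADRO = 6.02e23  # per mol, at the precision used for the reported figures


# ---------------------------------------------------------------------------
# karyotype


#: reference per-chromatid DNA contents (Mb, telomere-to-telomere assembly scale)
#: and conventional arm-ratio classes.
_REFERENCE_CHROMOSOMES = [
    # name, Mb per chromatid, class
    ("chr1", 248.4, "metacentric"),
    ("chr2", 242.7, "submetacentric"),
    ("chr3", 201.1, "metacentric"),
    ("chr4", 193.6, "submetacentric"),
    ("chr5", 182.0, "submetacentric"),
    ("chr6", 172.1, "submetacentric"),
    ("chr7", 160.6, "submetacentric"),
    ("chr8", 146.3, "submetacentric"),
    ("chr9", 150.6, "submetacentric"),
    ("chr10", 134.8, "submetacentric"),
    ("chr11", 135.1, "submetacentric"),
    ("chr12", 133.3, "submetacentric"),
    ("chr13", 113.6, "acrocentric"),
    ("chr14", 101.2, "acrocentric"),
    ("chr15", 99.8, "acrocentric"),
    ("chr16", 96.3, "metacentric"),
    ("chr17", 84.3, "submetacentric"),
    ("chr18", 80.5, "submetacentric"),
    ("chr19", 61.7, "metacentric"),
    ("chr20", 66.2, "metacentric"),
    ("chr21", 45.1, "acrocentric"),
    ("chr22", 51.3, "acrocentric"),
    ("chrX", 154.3, "submetacentric"),
]


@dataclass
class KaryotypeTable:
    """Per-chromosome DNA content (Mb per chromatid), copy number and class.

    ``replication_factor`` converts the unreplicated content to mitotic
    sister-chromatid content (2 for a replicated genome).
    """

    table: pd.DataFrame
    replication_factor: int = 2

    def __post_init__(self) -> None:
        required = {"name", "mb_per_chromatid", "copies", "expected_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"karyotype table missing columns: {sorted(missing)}")
        if (self.table["mb_per_chromatid"] <= 0).any():
            raise ValueError("DNA contents must be positive")
        if (self.table["copies"] < 1).any():
            raise ValueError("copy numbers must be >= 1")

    @classmethod
    def default_rpe1(cls) -> "KaryotypeTable":
        """Female diploid karyotype with the RPE1-clone trisomy 12 (47 chromosomes)."""
        rows = [
            {"name": n, "mb_per_chromatid": mb, "copies": 3 if n == "chr12" else 2, "expected_class": c}
            for n, mb, c in _REFERENCE_CHROMOSOMES
        ]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path: str | Path, replication_factor: int = 2) -> "KaryotypeTable":
        return cls(pd.read_csv(path), replication_factor=replication_factor)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def total_content_mb(self) -> float:
        """Total mitotic DNA content = sum Mb x copies x replication factor."""
        return float(
            (self.table["mb_per_chromatid"] * self.table["copies"]).sum() * self.replication_factor
        )

    @property
    def n_chromosomes(self) -> int:
        return int(self.table["copies"].sum())


def assign_identities(objects, karyotype: KaryotypeTable):
    """Assign chromosome names to the largest and smallest measured objects.

    Only the extremes of the length ranking can be identified
    unambiguously from relative size and centromere position, so the five
    largest and four smallest karyotype entries form the two candidate
    bands; objects are matched by length rank within each band, and only
    when the measured arm-ratio class agrees with the expectation.
    Mid-sized objects stay unassigned.  Assignment is injective per
    expected copy number.  The input objects are modified in place and
    returned.
    """
    from scipy.optimize import linear_sum_assignment

    measured = [o for o in objects if o.length is not None and o.length > 0]
    ranked = sorted(measured, key=lambda o: o.length, reverse=True)
    table = karyotype.table.sort_values("mb_per_chromatid", ascending=False)

    def band(entries, candidates):
        # slots ordered by expected size; candidates by measured size.  A
        # rank-distance assignment (class agreement required) tolerates the
        # rank swaps that measurement noise causes between near-equal
        # chromosomes while keeping the assignment injective per copy.
        slots = []
        for _, row in entries.iterrows():
            slots.extend([(row["name"], row["expected_class"])] * int(row["copies"]))
        candidates = candidates[: len(slots)]
        if not candidates:
            return
        forbidden = 1e9
        cost = np.full((len(candidates), len(slots)), forbidden)
        for i, obj in enumerate(candidates):
            for j, (_, expected) in enumerate(slots):
                if obj.morphology_class == expected:
                    cost[i, j] = (i - j) ** 2
        rows, cols = linear_sum_assignment(cost)
        for i, j in zip(rows, cols):
            if cost[i, j] < forbidden:
                candidates[i].identity = slots[j][0]

    band(table.head(5), ranked)  # largest: Chr1-5
    bottom = table.tail(4).iloc[::-1]  # smallest first: Chr19-22 band
    band(bottom, ranked[::-1])
    return objects


# ---------------------------------------------------------------------------
# densities


class PackingRatio(NamedTuple):
    per_chromosome: float  # Mb/µm of cohesed (two-chromatid) chromosome axis
    per_chromatid: float  # Mb/µm of a single chromatid


def linear_packing_ratio(
    lengths_um: Sequence[float], contents_mb: Sequence[float], through_origin: bool = True
) -> PackingRatio:
    """Linear DNA packing ratio (Mb/µm) from paired length/content data.

    The default fit is least squares through the origin (a zero-length
    chromosome carries zero DNA): slope = sum(c*l) / sum(l^2).  The
    per-chromatid ratio is slope/2 for cohesed chromosomes.
    """
    lengths = np.asarray(lengths_um, dtype=float)
    contents = np.asarray(contents_mb, dtype=float)
    if lengths.shape != contents.shape or lengths.size < 2:
        raise ValueError("need >= 2 paired (length, content) observations")
    if np.any(lengths <= 0):
        raise ValueError("all lengths must be positive")
    if through_origin:
        slope = float((contents * lengths).sum() / (lengths**2).sum())
    else:
        slope = float(np.polyfit(lengths, contents, 1)[0])
    return PackingRatio(per_chromosome=slope, per_chromatid=slope / 2.0)


def volumetric_density(total_mb: float, total_volume_um3: float) -> float:
    """Volumetric DNA density, Mb/µm³."""
    if total_mb <= 0:
        raise ValueError("DNA content must be positive")
    if total_volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return total_mb / total_volume_um3


# ---------------------------------------------------------------------------
# nucleosome arithmetic


@dataclass
class NucleosomeModel:
    """Nucleosome repeat model: 146 bp core + 49 bp linker = 195 bp.

    ``nucleosome_free_fraction`` discounts genome not in nucleosomes
    (ATAC-seq puts it near 0.3%, small enough that the default is 0;
    the parameter exists for sensitivity analysis).
    """

    bp_per_nucleosome: float = 195.0
    core_bp: float = 146.0
    linker_bp: float = 49.0
    nucleosome_free_fraction: float = 0.0
    avogadro: float = AVOGADRO
    occupied_volume_nm3: float | None = None  # per-nucleosome occupied volume, for CVC

    def __post_init__(self) -> None:
        if self.bp_per_nucleosome <= 0:
            raise ValueError("bp_per_nucleosome must be positive")
        if abs(self.core_bp + self.linker_bp - self.bp_per_nucleosome) > 1e-9:
            raise ValueError("core_bp + linker_bp must equal bp_per_nucleosome")
        if not 0.0 <= self.nucleosome_free_fraction < 1.0:
            raise ValueError("nucleosome_free_fraction must lie in [0, 1)")


@dataclass
class NucleosomeReport:
    """Densitometry chain outputs."""

    dna_density_mb_per_um3: float
    nucleosomes_per_um3: float
    volume_per_nucleosome_nm3: float
    cube_side_nm: float
    concentration_um: float  # micromolar
    cvc_percent: float | None = None

    def as_dict(self) -> dict:
        return {
            "dna_density_mb_per_um3": self.dna_density_mb_per_um3,
            "nucleosomes_per_um3": self.nucleosomes_per_um3,
            "volume_per_nucleosome_nm3": self.volume_per_nucleosome_nm3,
            "cube_side_nm": self.cube_side_nm,
            "concentration_um": self.concentration_um,
            "cvc_percent": self.cvc_percent,
        }


def nucleosome_metrics(dna_density_mb_per_um3: float, model: NucleosomeModel | None = None) -> NucleosomeReport:
    """DNA density (Mb/µm³) -> nucleosome number density, volume and molarity.

    nucleosomes/µm³ = density x 1e6 bp/Mb x (1 - NFR) / bp-per-nucleosome;
    each nucleosome then has 1e9 / (nucleosomes/µm³) nm³ available (side =
    cube root), and the molar concentration follows from Avogadro's number:
    µM = (nucleosomes/µm³) x 1e15 µm³/L / N_A x 1e6.
    """
    model = model or NucleosomeModel()
    if dna_density_mb_per_um3 <= 0:
        raise ValueError("DNA density must be positive")
    per_um3 = (
        dna_density_mb_per_um3 * 1e6 * (1.0 - model.nucleosome_free_fraction) / model.bp_per_nucleosome
    )
    vol_nm3 = 1e9 / per_um3
    concentration_um = per_um3 * 1e15 / model.avogadro * 1e6
    report = NucleosomeReport(
        dna_density_mb_per_um3=dna_density_mb_per_um3,
        nucleosomes_per_um3=per_um3,
        volume_per_nucleosome_nm3=vol_nm3,
        cube_side_nm=vol_nm3 ** (1.0 / 3.0),
        concentration_um=concentration_um,
    )
    if model.occupied_volume_nm3 is not None:
        report.cvc_percent = chromatin_volume_concentration(model.occupied_volume_nm3, report)
    return report


def chromatin_volume_concentration(occupied_nm3: float, report: NucleosomeReport) -> float:
    """CVC (%): fraction of the available per-nucleosome volume that is chromatin."""
    if occupied_nm3 <= 0:
        raise ValueError("occupied volume must be positive")
    cvc = 100.0 * occupied_nm3 / report.volume_per_nucleosome_nm3
    if cvc > 100.0:
        import warnings

        warnings.warn(
            f"occupied volume exceeds available volume (CVC = {cvc:.1f}%): "
            "the occupancy model is physically impossible",
            stacklevel=2,
        )
    return cvc


def shrinkage_volume_factor(linear_shrinkage_fraction: float) -> float:
    """Volume reduction from isotropic linear shrinkage: 1 - (1 - s)^3."""
    s = float(linear_shrinkage_fraction)
    if not 0.0 <= s < 1.0:
        raise ValueError("linear shrinkage fraction must lie in [0, 1)")
    return 1.0 - (1.0 - s) ** 3


def percent_reduction(before: float, after: float) -> float:
    """Percent decrease from ``before`` to ``after``."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return 100.0 * (before - after) / before


# ---------------------------------------------------------------------------
# nucleosome-free-region fraction from BED intervals


def merge_intervals(intervals):
    """Merge overlapping or touching half-open intervals per chromosome.

    Idempotent and order-invariant; returns intervals sorted by
    (chromosome, start).
    """
    by_chrom: dict[str, list] = {}
    for chrom, start, end in intervals:
        if end - start < 0:
            raise ValueError(f"negative-length interval ({chrom}, {start}, {end})")
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end:  # overlap or touching: merge
                cur_end = max(cur_end, end)
            else:
                merged.append((chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        merged.append((chrom, cur_start, cur_end))
    return merged


def nfr_fraction(intervals, genome_bp: float) -> float:
    """Merged interval coverage as a percentage of the genome length."""
    if genome_bp <= 0:
        raise ValueError("genome length must be positive")
    merged = merge_intervals(intervals)
    covered = sum(end - start for _, start, end in merged)
    return 100.0 * covered / genome_bp
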