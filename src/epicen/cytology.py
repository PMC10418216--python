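"""Statistics over scored-cell tables: mis-segregation rates, chromosome
attribution, cohesion dot classes, chromocenter and immunofluorescence
ratios, and fertility classes.

A mis-segregating cell is an anaphase cell with at least one lagging
chromosome; rates carry exact (Clopper-Pearson) 95% binomial intervals and
genotype contrasts use Fisher's exact test. Cohesion is read from prophase
FISH dot counts: 2 dots = sister chromatids cohered, 3-4 dots = cohesion
reduced; 1-dot nuclei are reported separately as unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import CytologyRecord

__all__ = [
    "FertilityObservation",
    "RateEstimate",
    "missegregation_rate",
    "compare_rates",
    "chromosome_attribution",
    "cohesion_classes",
    "chromocenter_fraction",
    "chromocenter_summary",
    "if_ratio",
    "fertility_class",
    "records_to_frame",
    "write_records",
    "read_records",
]


@dataclass
class FertilityObservation:
    """Seed availability and silique lengths for one plant."""

    plant_id: str
    silique_lengths_mm: list[float] = field(default_factory=list)
    seeds_per_plant: int | None = None

    def __post_init__(self) -> None:
        if any(x <= 0 for x in self.silique_lengths_mm):
            raise ValueError("silique lengths must be positive")
        if not self.silique_lengths_mm and self.seeds_per_plant is None:
            raise ValueError("need silique lengths or a seed count")


@dataclass
class RateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    n_abnormal: int
    n_scored: int


def _anaphase(records: list[CytologyRecord], genotype: str,
              ) -> list[CytologyRecord]:
    # FISH attribution experiments pre-select abnormal cells, so records
    # carrying a probe are excluded from rate estimation
    return [r for r in records
            if r.genotype == genotype and r.stage == "anaphase"
            and r.n_lagging is not None and r.fish_probe_chromosome is None]


def missegregation_rate(records: list[CytologyRecord], genotype: str,
                        confidence: float = 0.95) -> RateEstimate:
    """Fraction of anaphase cells with >= 1 lagging chromosome, with an
    exact Clopper-Pearson confidence interval."""
    cells = _anaphase(records, genotype)
    if not cells:
        raise ValueError(f"no anaphase records for genotype {genotype!r}")
    k = sum(1 for r in cells if r.n_lagging >= 1)
    n = len(cells)
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence,
                                             method="exact")
    return RateEstimate(k / n, float(ci.low), float(ci.high), k, n)


def compare_rates(records: list[CytologyRecord], genotype_a: str,
                  genotype_b: str) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 abnormal/normal table.

    Returns (p-value, rate difference a - b); symmetric in p under swapping
    the genotypes.
    """
    if genotype_a == genotype_b:
        raise ValueError("compare two distinct genotypes")
    table = []
    rates = []
    for g in (genotype_a, genotype_b):
        cells = _anaphase(records, g)
        if not cells:
            raise ValueError(f"no anaphase records for genotype {g!r}")
        k = sum(1 for r in cells if r.n_lagging >= 1)
        table.append([k, len(cells) - k])
        rates.append(k / len(cells))
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p), rates[0] - rates[1]


def chromosome_attribution(records: list[CytologyRecord],
                           genotype: str | None = None,
                           confidence: float = 0.95) -> pd.DataFrame:
    """Per-chromosome proportion of mis-segregation events colocalizing with
    that chromosome's FISH probe, among abnormal cells assayed with it.

    Probes are scored in separate experiments, so proportions need not sum
    to 1. A probe with no abnormal cells yields an undefined proportion
    (NaN, flagged).
    """
    rows = {}
    for r in records:
        if genotype is not None and r.genotype != genotype:
            continue
        if (r.stage != "anaphase" or not r.n_lagging
                or r.fish_probe_chromosome is None):
            continue
        k, n = rows.get(r.fish_probe_chromosome, (0, 0))
        rows[r.fish_probe_chromosome] = (k + bool(r.fish_colocalized), n + 1)
    out = []
    for chrom, (k, n) in sorted(rows.items()):
        if n == 0:
            out.append((chrom, np.nan, np.nan, np.nan, 0, True))
            continue
        ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence,
                                                 method="exact")
        out.append((chrom, k / n, float(ci.low), float(ci.high), n, False))
    return pd.DataFrame(out, columns=["chrom", "proportion", "ci_low",
                                      "ci_high", "n_abnormal", "undefined"])


def cohesion_classes(records: list[CytologyRecord], genotype: str,
                     ) -> dict[str, object]:
    """Histogram of prophase FISH dot counts and the reduced-cohesion
    fraction (3- or 4-dot nuclei among classifiable nuclei); 1-dot nuclei
    are reported separately as unclassified."""
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    for r in records:
        if r.genotype != genotype or r.fish_dot_count is None:
            continue
        if r.fish_dot_count not in counts:
            raise ValueError(f"dot count {r.fish_dot_count} outside 1-4")
        counts[r.fish_dot_count] += 1
    n = sum(counts.values())
    classifiable = counts[2] + counts[3] + counts[4]
    reduced = ((counts[3] + counts[4]) / classifiable if classifiable else
               float("nan"))
    return {"histogram": counts, "n": n, "reduced_fraction": reduced,
            "unclassified": counts[1]}


def chromocenter_fraction(record: CytologyRecord) -> float:
    """Proportion of nuclear signal concentrated in chromocenters."""
    if record.nucleus_intensity is None or record.nucleus_intensity <= 0:
        raise ValueError("record needs a positive nucleus intensity")
    cc = record.chromocenter_intensities or []
    total = float(sum(cc))
    if total > record.nucleus_intensity * (1 + 1e-9):
        raise ValueError("chromocenter signal exceeds nuclear signal "
                         "(segmentation inconsistency)")
    return total / record.nucleus_intensity


def chromocenter_summary(records: list[CytologyRecord],
                         ) -> pd.DataFrame:
    """Five-number summary of chromocenter fractions per genotype."""
    by_geno: dict[str, list[float]] = {}
    for r in records:
        if r.chromocenter_intensities is None or r.nucleus_intensity is None:
            continue
        by_geno.setdefault(r.genotype, []).append(chromocenter_fraction(r))
    rows = {}
    for g, vals in by_geno.items():
        a = np.asarray(vals)
        rows[g] = {"min": a.min(), "q1": np.percentile(a, 25),
                   "median": np.median(a), "q3": np.percentile(a, 75),
                   "max": a.max(), "n": a.size}
    return pd.DataFrame(rows).T


def if_ratio(record: CytologyRecord, kind: str) -> float:
    """Immunofluorescence ratios: H3K9me2/DAPI intensity, or H3T3ph dot size
    relative to the nucleus area."""
    if kind == "H3K9me2/DAPI":
        num, den = record.h3k9me2_intensity, record.dapi_intensity
    elif kind == "H3T3ph_dot_size":
        num, den = record.dot_area, record.nucleus_area
    else:
        raise ValueError(f"unknown ratio kind {kind!r}")
    if num is None or den is None:
        raise ValueError(f"record lacks the fields for {kind}")
    if den <= 0:
        raise ValueError("ratio denominator must be positive")
    return float(num) / float(den)


_SILIQUE_BINS = [  # half-open [lower, upper) silique-length bands
    (3.0, 5.0, "1-5 seeds / silique"),
    (5.0, 7.0, "5-10 seeds / silique"),
    (7.0, 9.0, "10-15 seeds / silique"),
    (9.0, 11.0, "15-20 seeds / silique"),
    (11.0, float("inf"), "> 20 seeds / silique"),
]


def fertility_class(obs: FertilityObservation) -> tuple[str, str]:
    """Fertility class from seed availability and silique length.

    A plant with 1-10 seeds is Sterile regardless of silique lengths.
    Otherwise the plant's representative (median) silique length is binned:
    [3,5) -> 1-5 seeds/silique, [5,7) -> 5-10, [7,9) -> 10-15,
    [9,11) -> 15-20, >= 11 -> > 20; below 3 mm -> Sterile.
    """
    if obs.seeds_per_plant is not None and obs.seeds_per_plant <= 10:
        return "Sterile", "1-10 seeds / plant"
    if not obs.silique_lengths_mm:
        return "Fertile", "unbinned (no silique lengths)"
    rep = float(np.median(obs.silique_lengths_mm))
    if rep < 3.0:
        return "Sterile", "< 3 mm siliques"
    for lo, hi, band in _SILIQUE_BINS:
        if lo <= rep < hi:
            return "Fertile", band
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# TSV I/O

def records_to_frame(records: list[CytologyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = vars(r).copy()
        cc = d.pop("chromocenter_intensities")
        d["chromocenter_intensities"] = (
            ",".join(f"{x:.4f}" for x in cc) if cc else "")
        rows.append(d)
    return pd.DataFrame(rows)


def write_records(records: list[CytologyRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records(path) -> list[CytologyRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        d = row.to_dict()
        cc = d.pop("chromocenter_intensities", "")
        d = {k: (None if pd.isna(v) else v) for k, v in d.items()}
        if isinstance(cc, str) and cc:
            d["chromocenter_intensities"] = [float(x) for x in cc.split(",")]
        else:
            d["chromocenter_intensities"] = None
        for int_field in ("n_lagging", "fish_dot_count"):
            if d.get(int_field) is not None:
                d[int_field] = int(d[int_field])
        if d.get("fish_colocalized") is not None:
            d["fish_colocalized"] = bool(d["fish_colocalized"])
        out.append(CytologyRecord(**d))
    return out
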