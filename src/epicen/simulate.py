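"""Synthetic methylomes and downstream readouts for the toy genome.

The generator emulates the study conditions the analyses assume:

* a triple RdRP mutant (``triple_mutant``) with wild-type-like heterochromatic
  methylation — heavily CG/CHG-methylated satellites and elements;
* the quadruple mutant (``quadruple_mutant``) that additionally lost the
  DDM1 remodeler: satellites lose CG and CHG methylation but retain CHH,
  while ATHILA elements lose CHH as well;
* epiallelic suppressors: quadruple background plus hypermethylation in all
  three contexts at one shared locus (and optional private loci);
* a hairpin line: quadruple background in which artificial small RNAs restore
  CHG and CHH — but never CG — methylation at the hairpin-homologous span of
  every ATHILA5 copy (RNA-directed methylation acts in trans on homology).

Coverage is Poisson per cytosine; methylated counts are Binomial around the
genotype's target level for the (annotation role, context) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import SimulationConfig, stream
from .genome import Annotation, ToyGenome
from .meth_io import CALL_COLUMNS

__all__ = [
    "GenotypeSpec",
    "EpigenotypeMosaic",
    "CytologyRecord",
    "SnpObservation",
    "triple_mutant",
    "quadruple_mutant",
    "suppressor_spec",
    "hairpin_spec",
    "suppressor_panel",
    "simulate_methylome",
    "simulate_recombinant_lines",
    "simulate_line_methylome",
    "simulate_chip_coverage",
    "simulate_cytology",
    "simulate_bsa_observations",
    "CHIP_MULTIPLIERS",
    "STRAIN_MISSEGREGATION_RATES",
]

_CTX = ("CG", "CHG", "CHH")


@dataclass
class GenotypeSpec:
    """Target methylation levels per (annotation role, context).

    ``hyper_loci`` are intervals hypermethylated in all three contexts (the
    epiallelic-suppressor gain); ``hairpin_restore`` switches on trans-acting
    CHG/CHH restoration at the hairpin-homologous span of every ATHILA5 copy.
    """

    name: str
    context_effects: dict[str, dict[str, float]]
    hyper_loci: list[tuple[str, int, int]] = field(default_factory=list)
    hyper_levels: dict[str, float] = field(
        default_factory=lambda: {"CG": 0.85, "CHG": 0.60, "CHH": 0.25})
    hairpin_restore: bool = False
    hairpin_levels: dict[str, float] = field(
        default_factory=lambda: {"CHG": 0.55, "CHH": 0.30})

    def __post_init__(self) -> None:
        for role, eff in self.context_effects.items():
            for ctx, level in eff.items():
                if not 0.0 <= level <= 1.0:
                    raise ValueError(
                        f"{self.name}: level for ({role},{ctx}) outside [0,1]")
        for d in (self.hyper_levels, self.hairpin_levels):
            for ctx, level in d.items():
                if not 0.0 <= level <= 1.0:
                    raise ValueError(f"{self.name}: level for {ctx} outside [0,1]")
        if "CG" in self.hairpin_levels:
            raise ValueError("hairpin restoration never raises CG methylation")

    def level(self, role: str, context: str) -> float:
        try:
            return self.context_effects[role][context]
        except KeyError:
            raise ValueError(
                f"genotype {self.name!r} has no target level for role "
                f"{role!r}, context {context!r}") from None


_EUCHROMATIN = {
    "gene": {"CG": 0.08, "CHG": 0.02, "CHH": 0.02},
    "intergenic": {"CG": 0.05, "CHG": 0.02, "CHH": 0.02},
}


def triple_mutant() -> GenotypeSpec:
    """rdr1;2;6-like: wild-type heterochromatic methylation."""
    return GenotypeSpec("triple", {
        "satellite_array": {"CG": 0.92, "CHG": 0.65, "CHH": 0.12},
        "ATHILA5": {"CG": 0.90, "CHG": 0.60, "CHH": 0.15},
        "ATHILA_other": {"CG": 0.90, "CHG": 0.60, "CHH": 0.15},
        **_EUCHROMATIN,
    })


def quadruple_mutant() -> GenotypeSpec:
    """rdr1;2;6 ddm1-like: satellites lose CG/CHG but retain CHH;
    ATHILA elements lose CHH as well (no easiRNA-directed methylation)."""
    return GenotypeSpec("quadruple", {
        "satellite_array": {"CG": 0.05, "CHG": 0.05, "CHH": 0.15},
        "ATHILA5": {"CG": 0.05, "CHG": 0.05, "CHH": 0.04},
        "ATHILA_other": {"CG": 0.05, "CHG": 0.05, "CHH": 0.04},
        **_EUCHROMATIN,
    })


def suppressor_spec(loci: list[tuple[str, int, int]],
                    name: str = "suppressor") -> GenotypeSpec:
    """Quadruple background plus all-context hypermethylation at ``loci``."""
    base = quadruple_mutant()
    return replace(base, name=name, hyper_loci=list(loci))


def hairpin_spec() -> GenotypeSpec:
    """Quadruple background with hairpin-restored CHG/CHH at ATHILA5 spans."""
    return replace(quadruple_mutant(), name="hairpin", hairpin_restore=True)


def suppressor_panel(genome: ToyGenome, config: SimulationConfig,
                     n_suppressors: int = 4, n_private: int = 5,
                     locus_width: int = 900) -> tuple[list[GenotypeSpec],
                                                      tuple[str, int, int]]:
    """Build suppressor genotypes sharing one hypermethylated locus.

    The shared locus covers the 5' region of the hairpin-source ATHILA5
    element, snapped to the 300 bp DMR grid; each suppressor additionally
    carries ``n_private`` private hypermethylated loci placed in the
    centromeres of the non-focal chromosomes.
    """
    src = genome.hairpin_source
    start = (src.start // 300) * 300
    shared = (src.chrom, start, start + locus_width)

    rng = stream(config.seed, "suppressor_panel")
    others = [c for c in genome.chrom_names if c != genome.focal_chrom]
    specs = []
    for i in range(n_suppressors):
        private: list[tuple[str, int, int]] = []
        while len(private) < n_private:
            chrom = others[rng.integers(len(others))]
            cs, ce = genome.centromeres[chrom]
            s = int(rng.integers(cs // 300, (ce - locus_width) // 300)) * 300
            cand = (chrom, s, s + locus_width)
            if all(c[0] != cand[0] or abs(c[1] - cand[1]) > 2 * locus_width
                   for c in private):
                private.append(cand)
        specs.append(suppressor_spec([shared] + private, name=f"sup_{i + 1}"))
    return specs, shared


# ---------------------------------------------------------------------------
# methylome simulation

def _hairpin_target_spans(genome: ToyGenome) -> list[tuple[str, int, int]]:
    """Hairpin-homologous span in every ATHILA5 copy (orientation-aware)."""
    hp = genome.hairpin_span
    src = genome.hairpin_source
    src_len = src.end - src.start
    if src.strand == "-":
        rel = ((src.end - hp.end) / src_len, (src.end - hp.start) / src_len)
    else:
        rel = ((hp.start - src.start) / src_len, (hp.end - src.start) / src_len)
    spans = []
    for el in genome.elements("ATHILA5"):
        elen = el.end - el.start
        if el.strand == "-":
            spans.append((el.chrom, el.end - int(rel[1] * elen),
                          el.end - int(rel[0] * elen)))
        else:
            spans.append((el.chrom, el.start + int(rel[0] * elen),
                          el.start + int(rel[1] * elen)))
    return spans


def _level_vector(genome: ToyGenome, genotype: GenotypeSpec,
                  chrom: str) -> np.ndarray:
    """Target methylation level for every retained cytosine on ``chrom``."""
    ctx_df = genome.contexts(chrom)
    pos = ctx_df["pos"].to_numpy()
    roles = genome.role_array(chrom)[pos]
    level = np.empty(pos.size, dtype=float)
    ctx = ctx_df["context"].to_numpy()
    for role in np.unique(roles):
        m = roles == role
        for c in _CTX:
            level[m & (ctx == c)] = genotype.level(str(role), c)

    if genotype.hairpin_restore:
        for span_chrom, s, e in _hairpin_target_spans(genome):
            if span_chrom != chrom:
                continue
            in_span = (pos >= s) & (pos < e)
            for c, lv in genotype.hairpin_levels.items():
                m = in_span & (ctx == c)
                level[m] = np.maximum(level[m], lv)

    for locus_chrom, s, e in genotype.hyper_loci:
        if locus_chrom != chrom:
            continue
        in_locus = (pos >= s) & (pos < e)
        for c in _CTX:
            lv = genotype.hyper_levels[c]
            m = in_locus & (ctx == c)
            level[m] = np.maximum(level[m], lv)
    return level


def _draw_calls(genome: ToyGenome, level_by_chrom: dict[str, np.ndarray],
                config: SimulationConfig, rng: np.random.Generator,
                ) -> pd.DataFrame:
    frames = []
    for chrom in genome.chrom_names:
        ctx_df = genome.contexts(chrom)
        level = level_by_chrom[chrom]
        total = rng.poisson(config.coverage_mean, size=level.size)
        keep = total > 0
        meth = np.zeros(level.size, dtype=np.int64)
        meth[keep] = rng.binomial(total[keep], level[keep])
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": ctx_df["pos"].to_numpy()[keep],
            "strand": ctx_df["strand"].to_numpy()[keep],
            "context": ctx_df["context"].to_numpy()[keep],
            "n_meth": meth[keep],
            "n_total": total[keep],
        }))
    return pd.concat(frames, ignore_index=True)[CALL_COLUMNS]


def simulate_methylome(genome: ToyGenome, genotype: GenotypeSpec,
                       config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a per-cytosine call table for one genotype.

    Coverage at each cytosine is Poisson(``coverage_mean``); the methylated
    count is Binomial(coverage, target level). Zero-coverage cytosines are
    not emitted. Calls are emitted for both strands.
    """
    if rng is None:
        rng = stream(config.seed, "methylome", genotype.name)
    levels = {chrom: _level_vector(genome, genotype, chrom)
              for chrom in genome.chrom_names}
    return _draw_calls(genome, levels, config, rng)


# ---------------------------------------------------------------------------
# epigenetic recombinant lines

@dataclass
class EpigenotypeMosaic:
    """Per-chromosome ddm1-derived / WT-derived block structure of one line."""

    line_id: str
    blocks: dict[str, list[tuple[int, int, str]]]  # (start, end, origin)
    phenotype: str  # "fertile" | "sterile"
    crossovers: dict[str, list[int]] = field(default_factory=dict)

    def origin_at(self, chrom: str, pos: int) -> str:
        for s, e, origin in self.blocks[chrom]:
            if s <= pos < e:
                return origin
        raise ValueError(f"position {chrom}:{pos} outside mosaic blocks")

    def spans(self, chrom: str, origin: str) -> list[tuple[int, int]]:
        return [(s, e) for s, e, o in self.blocks[chrom] if o == origin]


def _gamete_blocks(length: int, cen: tuple[int, int],
                   config: SimulationConfig, rng: np.random.Generator,
                   ) -> tuple[list[tuple[int, int, str]], list[int]]:
    """One meiotic product of a ddm1-derived / WT-derived heterozygote."""
    arm_len = length - (cen[1] - cen[0])
    n_arm = rng.poisson(config.crossover_rate_arm)
    n_cen = rng.poisson(config.crossover_rate_centromere)
    xovers: list[int] = []
    for _ in range(n_arm):
        u = int(rng.integers(arm_len))
        xovers.append(u if u < cen[0] else u + (cen[1] - cen[0]))
    xovers.extend(int(rng.integers(cen[0], cen[1])) for _ in range(n_cen))
    xovers = sorted(set(xovers))
    origin = "ddm1_derived" if rng.random() < 0.5 else "WT_derived"
    blocks = []
    prev = 0
    for x in xovers + [length]:
        if x > prev:
            blocks.append((prev, x, origin))
        origin = ("WT_derived" if origin == "ddm1_derived" else "ddm1_derived")
        prev = x
    return blocks, xovers


def simulate_recombinant_lines(genome: ToyGenome, config: SimulationConfig,
                               causative: tuple[str, int, int] | None = None,
                               rng: np.random.Generator | None = None,
                               n_lines: int | None = None,
                               ) -> list[EpigenotypeMosaic]:
    """Simulate epigenetic recombinant lines from the two-cross scheme.

    Each line's informative chromosome set is one meiotic product of a
    heterozygote carrying a fully ddm1-derived (hypomethylated) and a fully
    WT-derived homolog. The sterile epiallele is dominant: a line is sterile
    iff the causative interval is entirely ddm1-derived. The default
    causative interval is the hairpin-source ATHILA5 element.
    """
    n = n_lines if n_lines is not None else config.n_recombinant_lines
    if n <= 0:
        raise ValueError("at least one recombinant line must be requested")
    if rng is None:
        rng = stream(config.seed, "recombinants")
    if causative is None:
        src = genome.hairpin_source
        causative = (src.chrom, src.start, src.end)
    cchrom, cs, ce = causative

    lines = []
    for i in range(n):
        blocks: dict[str, list[tuple[int, int, str]]] = {}
        xo: dict[str, list[int]] = {}
        for name in genome.chrom_names:
            blocks[name], xo[name] = _gamete_blocks(
                genome.length(name), genome.centromeres[name], config, rng)
        cov = [(max(s, cs), min(e, ce)) for s, e, o in blocks[cchrom]
               if o == "ddm1_derived" and min(e, ce) > max(s, cs)]
        sterile = sum(e - s for s, e in cov) == ce - cs
        lines.append(EpigenotypeMosaic(f"line_{i + 1}", blocks,
                                       "sterile" if sterile else "fertile", xo))
    return lines


def genotype_level_vectors(genome: ToyGenome, genotype: GenotypeSpec,
                           ) -> dict[str, np.ndarray]:
    """Per-chromosome target-level vectors (precompute for panel loops)."""
    return {chrom: _level_vector(genome, genotype, chrom)
            for chrom in genome.chrom_names}


def simulate_line_methylome(genome: ToyGenome, mosaic: EpigenotypeMosaic,
                            config: SimulationConfig,
                            wt_like: GenotypeSpec | None = None,
                            ddm1_like: GenotypeSpec | None = None,
                            rng: np.random.Generator | None = None,
                            _levels: tuple[dict, dict] | None = None,
                            ) -> pd.DataFrame:
    """Compose a recombinant line's methylome from its block structure.

    ddm1-derived blocks follow the quadruple-mutant levels, WT-derived blocks
    the triple-mutant levels (the informative haplotype is simulated
    directly).
    """
    if rng is None:
        rng = stream(config.seed, "line_methylome", mosaic.line_id)
    if _levels is None:
        wt_levels = genotype_level_vectors(genome, wt_like or triple_mutant())
        dd_levels = genotype_level_vectors(genome,
                                           ddm1_like or quadruple_mutant())
    else:
        wt_levels, dd_levels = _levels
    levels = {}
    for chrom in genome.chrom_names:
        pos = genome.contexts(chrom)["pos"].to_numpy()
        is_ddm1 = np.zeros(pos.size, dtype=bool)
        for s, e in mosaic.spans(chrom, "ddm1_derived"):
            is_ddm1 |= (pos >= s) & (pos < e)
        levels[chrom] = np.where(is_ddm1, dd_levels[chrom], wt_levels[chrom])
    return _draw_calls(genome, levels, config, rng)


def simulate_mapping_panel(genome: ToyGenome, config: SimulationConfig,
                           causative: tuple[str, int, int] | None = None,
                           rng: np.random.Generator | None = None,
                           ) -> list[tuple[EpigenotypeMosaic, pd.DataFrame]]:
    """Simulate a full recombinant panel: mosaics plus per-line call tables."""
    if rng is None:
        rng = stream(config.seed, "mapping_panel")
    mosaics = simulate_recombinant_lines(genome, config, causative, rng)
    levels = (genotype_level_vectors(genome, triple_mutant()),
              genotype_level_vectors(genome, quadruple_mutant()))
    return [(m, simulate_line_methylome(genome, m, config, rng=rng,
                                        _levels=levels))
            for m in mosaics]


# ---------------------------------------------------------------------------
# ChIP-like coverage

CHIP_MULTIPLIERS = {
    "wt": {"satellite_array": 2.0, "ATHILA5": 4.0, "ATHILA_other": 4.0,
           "gene": 1.0, "intergenic": 1.0},
    "quadruple": {"satellite_array": 1.2, "ATHILA5": 1.2, "ATHILA_other": 1.2,
                  "gene": 1.0, "intergenic": 1.0},
    "hairpin": {"satellite_array": 1.2, "ATHILA5": 4.0, "ATHILA_other": 1.2,
                "gene": 1.0, "intergenic": 1.0},
}


def simulate_chip_coverage(genome: ToyGenome, multipliers: dict[str, float],
                           config: SimulationConfig, bin_size: int = 50,
                           input_depth: float = 20.0,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (IP, input) coverage tracks as gap-free binned bedGraphs.

    IP counts are Poisson around input_depth x role multiplier; input counts
    are Poisson(input_depth). Bin role is taken at the bin midpoint.
    """
    if any(m < 0 for m in multipliers.values()):
        raise ValueError("enrichment multipliers must be non-negative")
    if rng is None:
        rng = stream(config.seed, "chip")
    ip_frames, in_frames = [], []
    for chrom in genome.chrom_names:
        L = genome.length(chrom)
        starts = np.arange(0, L, bin_size)
        ends = np.minimum(starts + bin_size, L)
        mids = (starts + ends) // 2
        roles = genome.role_array(chrom)[mids]
        mult = np.empty(starts.size)
        for role in np.unique(roles):
            if str(role) not in multipliers:
                raise ValueError(f"no multiplier for role {role!r}")
            mult[roles == role] = multipliers[str(role)]
        ip = rng.poisson(input_depth * mult)
        inp = rng.poisson(input_depth, size=starts.size)
        ip_frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": ends, "value": ip}))
        in_frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                       "end": ends, "value": inp}))
    return (pd.concat(ip_frames, ignore_index=True),
            pd.concat(in_frames, ignore_index=True))


# ---------------------------------------------------------------------------
# cytology

@dataclass
class CytologyRecord:
    """One scored cell (anaphase lagging counts or prophase FISH/intensities)."""

    genotype: str
    cell_id: str
    stage: str  # "anaphase" | "prophase"
    n_lagging: int | None = None
    fish_probe_chromosome: str | None = None
    fish_colocalized: bool | None = None
    fish_dot_count: int | None = None
    chromocenter_intensities: list[float] | None = None
    nucleus_intensity: float | None = None
    h3k9me2_intensity: float | None = None
    dapi_intensity: float | None = None
    dot_area: float | None = None
    nucleus_area: float | None = None


STRAIN_MISSEGREGATION_RATES = {
    "WT": 0.0, "rdr1;2": 0.0, "rdr1;2;6": 0.0, "rdr1;2 ddm1": 0.0,
    "rdr1;2;6 ddm1": 0.31, "rdr1;2;6 ddm1 hp5": 0.03,
    "tailswap cenh3": 0.19, "episuppressor 3-75": 0.18,
    "rdr1;2 ddm1 kyp": 0.13, "rdr1;2 kyp": 0.0,
}

_COHESION_REDUCED = {  # P(cohesion reduced: 3-4 FISH dots) per genotype
    "rdr1;2;6 ddm1": 0.60, "rdr1;2;6 ddm1 hp5": 0.10,
}
_CHROMOCENTER_FRAC = {  # mean chromocenter fraction of nuclear signal
    "rdr1;2;6 ddm1": 0.06,
}


def simulate_cytology(config: SimulationConfig,
                      rates: dict[str, float] | None = None,
                      chr5_bias: float = 0.84,
                      rng: np.random.Generator | None = None,
                      ) -> list[CytologyRecord]:
    """Simulate scored cells for each genotype.

    Per genotype: ``n_cells_scored`` anaphase records with Bernoulli lagging
    events, each event attributed to the focal chromosome with probability
    ``chr5_bias`` (else uniform over the others); 50 prophase FISH records
    with 1-4 cohesion dots; and nuclei with chromocenter/whole-nucleus
    intensities plus H3K9me2/DAPI pairs.
    """
    if not 0.0 <= chr5_bias <= 1.0:
        raise ValueError("chr5_bias must lie in [0, 1]")
    rates = STRAIN_MISSEGREGATION_RATES if rates is None else rates
    if any(not 0.0 <= p <= 1.0 for p in rates.values()):
        raise ValueError("mis-segregation probabilities must lie in [0, 1]")
    if rng is None:
        rng = stream(config.seed, "cytology")

    chroms = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]
    focal = chroms[-1]
    others = chroms[:-1]
    records: list[CytologyRecord] = []
    for genotype, p in rates.items():
        # anaphase scoring of the mis-segregation rate
        for i in range(config.n_cells_scored):
            records.append(CytologyRecord(
                genotype, f"{genotype}_ana_{i + 1}", "anaphase",
                n_lagging=int(rng.random() < p)))
        # FISH attribution: a separate experiment per probe chromosome,
        # scoring n_cells_scored abnormal cells each (only meaningful for
        # genotypes that mis-segregate at all)
        if p > 0:
            for probe in chroms:
                for i in range(config.n_cells_scored):
                    event_chrom = (focal if rng.random() < chr5_bias
                                   else others[rng.integers(len(others))])
                    records.append(CytologyRecord(
                        genotype, f"{genotype}_fish_{probe}_{i + 1}",
                        "anaphase", n_lagging=1,
                        fish_probe_chromosome=probe,
                        fish_colocalized=event_chrom == probe))
        # prophase cohesion FISH (50 nuclei per genotype)
        reduced_p = _COHESION_REDUCED.get(genotype, 0.05)
        for i in range(50):
            u = rng.random()
            if u < 0.02:
                dots = 1
            elif u < 0.02 + reduced_p:
                dots = 3 if rng.random() < 0.6 else 4
            else:
                dots = 2
            records.append(CytologyRecord(
                genotype, f"{genotype}_pro_{i + 1}", "prophase",
                fish_dot_count=dots))
        # chromocenter and immunofluorescence intensities
        cc_frac = _CHROMOCENTER_FRAC.get(genotype, 0.18)
        n_nuclei = max(1, config.n_chromocenters // 10)
        for i in range(n_nuclei):
            cc = rng.gamma(4.0, 25.0, size=10)
            nucleus = float(cc.sum() / max(cc_frac * rng.normal(1.0, 0.1), 1e-3))
            nucleus = max(nucleus, float(cc.sum()))
            dapi = float(rng.gamma(5.0, 20.0))
            k9_ratio = 0.2 if genotype in _CHROMOCENTER_FRAC else 0.8
            records.append(CytologyRecord(
                genotype, f"{genotype}_nuc_{i + 1}", "prophase",
                chromocenter_intensities=[float(x) for x in cc],
                nucleus_intensity=nucleus,
                h3k9me2_intensity=dapi * k9_ratio * float(rng.normal(1, 0.1)),
                dapi_intensity=dapi,
                dot_area=float(rng.gamma(3.0, 1.0)),
                nucleus_area=float(rng.gamma(8.0, 25.0)) + 50.0))
    return records


# ---------------------------------------------------------------------------
# bulked-segregant SNP pools

@dataclass
class SnpObservation:
    """Pooled allele counts for one EMS-induced SNP."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_suppressor: int
    depth_suppressor: int
    alt_nonsuppressor: int
    depth_nonsuppressor: int

    def __post_init__(self) -> None:
        if (self.alt_suppressor > self.depth_suppressor
                or self.alt_nonsuppressor > self.depth_nonsuppressor):
            raise ValueError("allele count exceeds pool depth")


def simulate_bsa_observations(genome: ToyGenome, config: SimulationConfig,
                              n_snps: int = 40, depth: float = 50.0,
                              causal_pos: int | None = None,
                              map_expected_crossovers: float = 4.0,
                              rng: np.random.Generator | None = None,
                              ) -> tuple[list[SnpObservation], int]:
    """Simulate suppressor/non-suppressor pools over EMS-induced SNPs.

    The causal SNP is a recessive suppressor in the focal centromere: all
    15 suppressor-pool plants are homozygous mutant (allele frequency 1)
    while the 45 non-suppressors segregate MM:Mm = 1:2 (expected frequency
    1/3). Other SNPs were heterozygous in the pooled plants' parent; SNPs on
    the focal chromosome co-segregate with the causal one at a Haldane
    recombination fraction derived from their physical distance (map length
    = crossover_rate_arm per chromosome), SNPs elsewhere are unlinked. Read
    counts are Binomial around each pool's sampled allele frequency at
    Poisson depth. The EMS signature G->A is used for every SNP.
    """
    if rng is None:
        rng = stream(config.seed, "bsa")
    n_sup, n_non = config.suppressor_pool_sizes
    focal = genome.focal_chrom
    L = genome.length(focal)
    cs, ce = genome.centromeres[focal]
    if causal_pos is None:
        causal_pos = (cs + ce) // 2

    per_chrom = max(1, n_snps // len(genome.chrom_names))
    positions: list[tuple[str, int]] = [(focal, causal_pos)]
    for chrom in genome.chrom_names:
        pos = rng.integers(0, genome.length(chrom), size=per_chrom)
        positions.extend((chrom, int(p)) for p in pos if
                         (chrom, int(p)) != (focal, causal_pos))
    positions.sort()

    lam = map_expected_crossovers / L  # expected crossovers per bp
    obs = []
    for chrom, pos in positions:
        if chrom == focal:
            d = abs(pos - causal_pos)
            r = 0.5 * (1.0 - np.exp(-2.0 * lam * d))  # Haldane
        else:
            r = 0.5
        # suppressor plants are mm at the causal locus: each gamete carries
        # the mutant allele at a linked SNP with probability 1 - r
        alt_sup_alleles = rng.binomial(2 * n_sup, 1.0 - r)
        af_sup = alt_sup_alleles / (2 * n_sup)
        # non-suppressors are MM (1/3) or Mm (2/3) at the causal locus
        n_MM = rng.binomial(n_non, 1 / 3)
        alleles = (rng.binomial(2 * n_MM, r)
                   + rng.binomial(n_non - n_MM, 1.0 - r)   # m-bearing gamete
                   + rng.binomial(n_non - n_MM, r))        # M-bearing gamete
        af_non = alleles / (2 * n_non)
        d_sup = max(1, int(rng.poisson(depth)))
        d_non = max(1, int(rng.poisson(depth)))
        obs.append(SnpObservation(chrom, pos, "G", "A",
                                  int(rng.binomial(d_sup, af_sup)), d_sup,
                                  int(rng.binomial(d_non, af_non)), d_non))
    return obs, causal_pos
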