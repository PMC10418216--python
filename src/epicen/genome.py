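"""Toy genome with centromeric satellite arrays and embedded retrotransposons.

The default layout mimics the organisation of an Arabidopsis-like genome at
desk scale: 5 chromosomes, each with a central centromere tiled by ~180 bp
satellite monomer repeats. The focal chromosome (the last one, "Chr5" by
default) carries several ATHILA5 retrotransposon copies embedded in its
centromeric satellites, alongside other ATHILA elements; every chromosome
carries a few additional ATHILA elements and arm genes. One ATHILA5 copy on
the focal chromosome hosts the hairpin span — the region an artificial
small-RNA hairpin is built from.

Coordinates are 0-based half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig, stream
from .meth_io import classify_contexts

__all__ = ["Annotation", "ToyGenome", "build_toy_genome", "ROLES"]

ROLES = ("satellite_array", "ATHILA5", "ATHILA_other", "gene", "hairpin_span")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Annotation:
    chrom: str
    start: int
    end: int
    role: str
    strand: str = "+"
    name: str = "."


@dataclass
class ToyGenome:
    chromosomes: list[tuple[str, str]]
    annotations: list[Annotation]
    centromeres: dict[str, tuple[int, int]]
    focal_chrom: str
    _context_cache: dict = field(default_factory=dict, repr=False)
    _role_cache: dict = field(default_factory=dict, repr=False)

    # -- access helpers ----------------------------------------------------
    @property
    def chrom_names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]

    def sequence(self, chrom: str) -> str:
        for name, seq in self.chromosomes:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def elements(self, role: str, chrom: str | None = None) -> list[Annotation]:
        return [a for a in self.annotations
                if a.role == role and (chrom is None or a.chrom == chrom)]

    @property
    def hairpin_span(self) -> Annotation:
        spans = self.elements("hairpin_span")
        if len(spans) != 1:
            raise ValueError("genome must carry exactly one hairpin span")
        return spans[0]

    @property
    def hairpin_source(self) -> Annotation:
        """The ATHILA5 element containing the hairpin span."""
        hp = self.hairpin_span
        for a in self.elements("ATHILA5", hp.chrom):
            if a.start <= hp.start and hp.end <= a.end:
                return a
        raise ValueError("hairpin span is not contained in an ATHILA5 element")

    def contexts(self, chrom: str) -> pd.DataFrame:
        """Cached per-cytosine (strand, context) assignment for a chromosome."""
        if chrom not in self._context_cache:
            df = classify_contexts(self.sequence(chrom), chrom=chrom)
            self._context_cache[chrom] = df[df["context"] != "undetermined"
                                            ].reset_index(drop=True)
        return self._context_cache[chrom]

    def role_array(self, chrom: str) -> np.ndarray:
        """Per-base annotation role, object array; unannotated = 'intergenic'.

        Elements take precedence over the satellite arrays they are embedded
        in; the hairpin span is an overlay, not a methylation role.
        """
        if chrom not in self._role_cache:
            roles = np.full(self.length(chrom), "intergenic", dtype=object)
            for pass_roles in (("satellite_array",),
                               ("gene", "ATHILA5", "ATHILA_other")):
                for a in self.annotations:
                    if a.chrom == chrom and a.role in pass_roles:
                        roles[a.start:a.end] = a.role
            self._role_cache[chrom] = roles
        return self._role_cache[chrom]

    def validate(self) -> None:
        lengths = {name: len(seq) for name, seq in self.chromosomes}
        for a in self.annotations:
            if a.chrom not in lengths:
                raise ValueError(f"annotation on unknown chromosome {a.chrom}")
            if not (0 <= a.start < a.end <= lengths[a.chrom]):
                raise ValueError(f"annotation {a} outside its chromosome")
        hp = self.hairpin_span
        src = self.hairpin_source  # raises if not contained
        assert src.chrom == hp.chrom

    # -- writers -----------------------------------------------------------
    def write_fasta(self, path, width: int = 70) -> None:
        from Bio import SeqIO
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in self.chromosomes]
        if hasattr(path, "write"):
            SeqIO.write(records, path, "fasta")
        else:
            with open(path, "w") as fh:
                SeqIO.write(records, fh, "fasta")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for a in sorted(self.annotations, key=lambda x: (x.chrom, x.start)):
                fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.role}:{a.name}"
                         f"\t0\t{a.strand}\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name, seq in self.chromosomes:
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
            for a in sorted(self.annotations, key=lambda x: (x.chrom, x.start)):
                fh.write(f"{a.chrom}\tepicen\t{a.role}\t{a.start + 1}\t{a.end}"
                         f"\t.\t{a.strand}\t.\tID={a.name};role={a.role}\n")

    def annotations_df(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.annotations])


def _satellite_fill(rng: np.random.Generator, monomer: np.ndarray,
                    length: int, offset: int) -> np.ndarray:
    """Tile a satellite monomer, with 2% divergence between copies."""
    reps = int(np.ceil((length + offset) / monomer.size)) + 1
    tiled = np.tile(monomer, reps)[offset:offset + length].copy()
    mut = rng.random(length) < 0.02
    tiled[mut] = _BASES[rng.integers(0, 4, size=int(mut.sum()))]
    return tiled


def build_toy_genome(config: SimulationConfig,
                     n_athila5: int = 3,
                     n_athila_other_focal: int = 3,
                     athila5_length: int = 2400,
                     athila_other_length: int = 1800,
                     gene_length: int = 1200,
                     arm_te_length: int = 1500,
                     hairpin_rel_span: tuple[float, float] = (0.1, 0.9),
                     ) -> ToyGenome:
    """Build the deterministic toy genome for a configuration.

    Centromeres span the central 40% of each chromosome and are tiled by a
    180 bp satellite monomer except where elements are embedded. The focal
    (last) chromosome carries ``n_athila5`` ATHILA5 and
    ``n_athila_other_focal`` other ATHILA copies in its centromere; the other
    chromosomes carry two centromeric ATHILA copies each. Every chromosome
    has one arm ATHILA element per arm and three genes per arm.
    """

    if config.chrom_length < 10_000:
        raise ValueError("chromosome length must be >= 10 kb")
    if n_athila5 < 2 or n_athila_other_focal < 2:
        raise ValueError("focal chromosome needs >= 2 ATHILA5 and >= 2 other "
                         "ATHILA elements")

    rng = stream(config.seed, "toy_genome")
    L = config.chrom_length
    cen = (int(0.3 * L), int(0.7 * L))
    cen_len = cen[1] - cen[0]
    monomer = _BASES[rng.integers(0, 4, size=180)]

    chromosomes: list[tuple[str, str]] = []
    annotations: list[Annotation] = []
    centromeres: dict[str, tuple[int, int]] = {}
    names = [f"Chr{i + 1}" for i in range(config.n_chromosomes)]
    focal = names[-1]

    for name in names:
        seq = _BASES[rng.integers(0, 4, size=L)]
        centromeres[name] = cen

        # centromeric elements, evenly spaced
        if name == focal:
            roles = (["ATHILA5"] * n_athila5 +
                     ["ATHILA_other"] * n_athila_other_focal)
            order = rng.permutation(len(roles))
            roles = [roles[i] for i in order]
        else:
            roles = ["ATHILA_other"] * 2
        lengths = [athila5_length if r == "ATHILA5" else athila_other_length
                   for r in roles]
        if max(lengths, default=0) > cen_len:
            raise ValueError("element longer than the centromere interval")
        if sum(lengths) >= cen_len:
            raise ValueError("elements do not fit in the centromere interval")
        gap = (cen_len - sum(lengths)) // (len(roles) + 1)
        pos = cen[0] + gap
        elements: list[Annotation] = []
        k5 = ko = 0
        for role, elen in zip(roles, lengths):
            strand = "+" if rng.random() < 0.5 else "-"
            if role == "ATHILA5":
                k5 += 1
                ename = f"{name}_ATHILA5_{k5}"
            else:
                ko += 1
                ename = f"{name}_ATHILA_{ko}"
            elements.append(Annotation(name, pos, pos + elen, role, strand, ename))
            seq[pos:pos + elen] = _BASES[rng.integers(0, 4, size=elen)]
            pos += elen + gap

        # satellite arrays tile the centromere between/around elements
        edges = [cen[0]] + [x for a in elements for x in (a.start, a.end)] + [cen[1]]
        sat_i = 0
        for s, e in zip(edges[::2], edges[1::2]):
            if e - s >= monomer.size:
                sat_i += 1
                seq[s:e] = _satellite_fill(rng, monomer, e - s, s % monomer.size)
                annotations.append(Annotation(name, s, e, "satellite_array",
                                              "+", f"{name}_sat_{sat_i}"))
        annotations.extend(elements)

        # one ATHILA element per arm
        for j, arm_pos in enumerate((int(0.08 * L), int(0.88 * L))):
            strand = "+" if rng.random() < 0.5 else "-"
            annotations.append(Annotation(name, arm_pos, arm_pos + arm_te_length,
                                          "ATHILA_other", strand,
                                          f"{name}_armTE_{j + 1}"))

        # three genes per arm
        gi = 0
        for arm_start, arm_end in ((0, cen[0]), (cen[1], L)):
            for frac in (0.25, 0.5, 0.75):
                gi += 1
                gs = arm_start + int(frac * (arm_end - arm_start))
                strand = "+" if rng.random() < 0.5 else "-"
                annotations.append(Annotation(name, gs, gs + gene_length,
                                              "gene", strand,
                                              f"{name}_gene_{gi}"))
        chromosomes.append((name, seq.tobytes().decode("ascii")))

    genome = ToyGenome(chromosomes, annotations, centromeres, focal)
    src = genome.elements("ATHILA5", focal)[0]
    a, b = hairpin_rel_span
    hp = Annotation(focal,
                    src.start + int(a * (src.end - src.start)),
                    src.start + int(b * (src.end - src.start)),
                    "hairpin_span", src.strand, "hp5")
    genome.annotations.append(hp)
    genome.validate()
    return genome
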