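"""Mapping a heritable phenotype to a hypomethylated chromosomal region.

Four complementary strategies, mirroring how such epialleles are mapped in
practice:

* **pooled-window comparison** — average fixed-window methylation of the
  fertile and sterile line groups and scan for runs where the fertile pool
  exceeds the sterile pool (the sterile pool is hypomethylated where linked);
* **marker epigenotyping** — classify a chromosomal region as ddm1-derived
  (hypomethylated) or WT-derived from its local methylation level, the in
  silico analogue of an McrBC digestion/PCR readout;
* **interval logic** — the minimal interval consistent with a dominant
  causative epiallele across recombinant lines;
* **bulked-segregant SNP scan** — allele-frequency difference between
  suppressor and non-suppressor pools (expected 1 vs 1/3 for a recessive
  suppressor under 15/45 pooling), plus CAPS restriction-site checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .dmr import window_methylation
from .simulate import SnpObservation

__all__ = [
    "MarkerCall",
    "MapResult",
    "pool_profiles",
    "linked_region_scan",
    "epigenotype_markers",
    "map_interval",
    "bsa_snp_scan",
    "bsa_peak_region",
    "caps_check",
]


# ---------------------------------------------------------------------------
# pooled-window mapping

def pool_profiles(fertile_calls: list[pd.DataFrame],
                  sterile_calls: list[pd.DataFrame],
                  width: int = 100_000) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group mean window profiles, lines weighted equally.

    Each line is windowed individually; the group level per window is the
    unweighted mean of the per-line levels (NaN-aware).
    """
    out = []
    for group in (fertile_calls, sterile_calls):
        if not group:
            raise ValueError("each phenotype group needs at least one line")
        profs = [window_methylation(c, width) for c in group]
        merged = pd.concat(profs).groupby(["chrom", "start", "end"],
                                          sort=True).mean()
        out.append(merged.reset_index())
    return out[0], out[1]


def linked_region_scan(fertile: pd.DataFrame, sterile: pd.DataFrame,
                       delta_min: float = 0.2) -> pd.DataFrame:
    """Maximal runs of windows where fertile - sterile >= delta_min.

    Candidates are ranked by run length x mean delta; the top row is the
    linked-region candidate. An empty frame (no window above delta_min) is a
    valid null result.
    """
    m = fertile.merge(sterile, on=["chrom", "start", "end"],
                      suffixes=("_fertile", "_sterile"))
    delta = (m["total_level_fertile"] - m["total_level_sterile"]).to_numpy(float)
    hit = delta >= delta_min

    runs = []
    m = m.assign(delta=delta, hit=hit).sort_values(["chrom", "start"])
    width = int((m["end"] - m["start"]).iloc[0]) if len(m) else 0
    for chrom, grp in m.groupby("chrom", sort=True):
        start = None
        deltas: list[float] = []
        prev_end = None
        for _, row in grp.iterrows():
            contiguous = prev_end is not None and row["start"] == prev_end
            if row["hit"] and start is not None and contiguous:
                deltas.append(row["delta"])
                prev_end = row["end"]
            elif row["hit"]:
                if start is not None:
                    runs.append((chrom, start, prev_end, deltas))
                start = row["start"]
                deltas = [row["delta"]]
                prev_end = row["end"]
            else:
                if start is not None:
                    runs.append((chrom, start, prev_end, deltas))
                    start = None
                prev_end = row["end"] if not row["hit"] else prev_end
        if start is not None:
            runs.append((chrom, start, prev_end, deltas))

    rows = [(chrom, int(s), int(e), len(d), float(np.mean(d)),
             len(d) * float(np.mean(d)))
            for chrom, s, e, d in runs]
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_windows",
                                      "mean_delta", "score"])
    return out.sort_values("score", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# marker epigenotyping

@dataclass
class MarkerCall:
    """Thresholded methylation state at one marker position."""

    chrom: str
    pos: int
    line_id: str
    call: str  # "ddm1_derived" | "WT_derived" | "ambiguous"
    evidence: float  # local methylation level (NaN when uncovered)
    flagged: bool = False


def epigenotype_markers(calls: pd.DataFrame, markers: list[tuple[str, int]],
                        line_id: str = "", window: int = 2000,
                        low: float = 0.2, high: float = 0.5,
                        contexts: tuple[str, ...] = ("CG",),
                        ) -> list[MarkerCall]:
    """Classify each marker from the pooled methylation level around it.

    Level = sum(n_meth)/sum(n_total) over the chosen contexts within
    +-window/2 of the marker. Below ``low`` -> ddm1_derived, above ``high``
    -> WT_derived, otherwise ambiguous. Markers in uncovered regions are
    ambiguous and flagged.
    """
    df = calls[calls["context"].isin(contexts)]
    half = window // 2
    # windowed sums per chromosome via sorted-position cumsums
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        pos = grp["pos"].to_numpy()[order]
        cm = np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy()[order])])
        ct = np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy()[order])])
        by_chrom[chrom] = (pos, cm, ct)

    out = []
    for chrom, pos in markers:
        if chrom not in by_chrom:
            out.append(MarkerCall(chrom, pos, line_id, "ambiguous",
                                  float("nan"), flagged=True))
            continue
        p, cm, ct = by_chrom[chrom]
        lo = np.searchsorted(p, pos - half, side="left")
        hi = np.searchsorted(p, pos + half, side="left")
        total = int(ct[hi] - ct[lo])
        if total == 0:
            out.append(MarkerCall(chrom, pos, line_id, "ambiguous",
                                  float("nan"), flagged=True))
            continue
        level = float(cm[hi] - cm[lo]) / total
        if level < low:
            call = "ddm1_derived"
        elif level > high:
            call = "WT_derived"
        else:
            call = "ambiguous"
        out.append(MarkerCall(chrom, pos, line_id, call, level))
    return out


# ---------------------------------------------------------------------------
# interval logic

@dataclass
class MapResult:
    chrom: str
    interval: tuple[int, int] | None
    status: str  # "mapped" | "unresolved" | "inconsistent"
    intervals: list[tuple[int, int]] = field(default_factory=list)
    violations: list[str] = field(default_factory=list)


def _line_spans(calls: list[MarkerCall], chrom: str, chrom_length: int,
                generous: bool) -> list[tuple[int, int]]:
    """ddm1-derived spans implied by one line's ordered marker calls.

    ``generous`` spans extend each ddm1-derived run outward to the nearest
    discordant (WT-derived) marker or chromosome end; conservative spans
    cover only the run between the outermost ddm1-derived markers (markers
    inclusive). Ambiguous markers separate nothing.
    """
    ordered = sorted((c for c in calls if c.chrom == chrom),
                     key=lambda c: c.pos)
    spans = []
    i = 0
    informative = [c for c in ordered if c.call != "ambiguous"]
    while i < len(informative):
        if informative[i].call != "ddm1_derived":
            i += 1
            continue
        j = i
        while j + 1 < len(informative) and \
                informative[j + 1].call == "ddm1_derived":
            j += 1
        if generous:
            left = 0 if i == 0 else informative[i - 1].pos + 1
            right = (chrom_length if j == len(informative) - 1
                     else informative[j + 1].pos)
        else:
            left = informative[i].pos
            right = informative[j].pos + 1
        spans.append((left, right))
        i = j + 1
    return iv.merge(spans)


def map_interval(lines: list[tuple[list[MarkerCall], str]], chrom: str,
                 chrom_length: int) -> MapResult:
    """Minimal interval consistent with a dominant causative epiallele.

    Intersection over sterile lines of their (generously bounded)
    ddm1-derived spans, minus the union over fertile lines of their
    (conservatively bounded) ddm1-derived spans. An empty intersection
    yields an inconsistency report naming the violating lines; no
    informative sterile recombinant yields the whole region, flagged
    unresolved.
    """
    sterile = [(mc, _line_spans(mc, chrom, chrom_length, generous=True))
               for mc, ph in lines if ph == "sterile"]
    fertile = [(mc, _line_spans(mc, chrom, chrom_length, generous=False))
               for mc, ph in lines if ph == "fertile"]

    if not sterile:
        return MapResult(chrom, (0, chrom_length), "unresolved",
                         [(0, chrom_length)])

    candidate = [(0, chrom_length)]
    violations = []
    for mc, spans in sterile:
        if not spans:
            violations.append(mc[0].line_id if mc else "?")
            continue
        candidate = iv.intersect(candidate, spans)
    if not candidate:
        return MapResult(chrom, None, "inconsistent",
                         violations=[mc[0].line_id for mc, s in sterile if mc])

    for mc, spans in fertile:
        remaining = iv.subtract(candidate, spans)
        if not remaining:
            violations.append(mc[0].line_id if mc else "?")
            continue  # subtracting would erase the candidate: contradiction
        candidate = remaining

    if not candidate:
        return MapResult(chrom, None, "inconsistent", violations=violations)
    status = "inconsistent" if violations else "mapped"
    top = max(candidate, key=lambda x: x[1] - x[0])
    return MapResult(chrom, top, status, candidate, violations)


# ---------------------------------------------------------------------------
# bulked-segregant SNP scan

def bsa_snp_scan(observations: list[SnpObservation], window: int = 10_000,
                 step: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed allele-frequency difference between pools.

    Per SNP, delta-AF = AF_suppressor - AF_nonsuppressor (expected 2/3 at
    the causal SNP under the 15/45 recessive design, ~0 for unlinked SNPs).
    Windows of ``window`` bp slide by ``step`` bp (default window/2; the
    overlap keeps a linked SNP cluster from being split across window
    boundaries). Returns (per-SNP table, windowed profile sorted by
    descending mean delta); the first profile row is the peak region.
    Zero-depth SNPs are skipped.
    """
    if step is None:
        step = max(1, window // 2)
    rows = []
    for o in observations:
        if o.depth_suppressor == 0 or o.depth_nonsuppressor == 0:
            continue
        af_s = o.alt_suppressor / o.depth_suppressor
        af_n = o.alt_nonsuppressor / o.depth_nonsuppressor
        rows.append((o.chrom, o.pos, af_s, af_n, af_s - af_n))
    snps = pd.DataFrame(rows, columns=["chrom", "pos", "af_suppressor",
                                       "af_nonsuppressor", "delta_af"])
    if snps.empty:
        return snps, pd.DataFrame(columns=["chrom", "start", "end",
                                           "n_snps", "mean_delta"])

    win_rows = []
    for chrom, grp in snps.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        delta = grp["delta_af"].to_numpy()
        first = int(pos.min()) // step
        last = int(pos.max()) // step
        for k in range(max(0, first - window // step + 1), last + 1):
            start = k * step
            m = (pos >= start) & (pos < start + window)
            if m.any():
                win_rows.append((chrom, start, start + window,
                                 int(m.sum()), float(delta[m].mean())))
    prof = pd.DataFrame(win_rows, columns=["chrom", "start", "end",
                                           "n_snps", "mean_delta"])
    return snps, \
        prof.sort_values("mean_delta", ascending=False).reset_index(drop=True)


def bsa_peak_region(profile: pd.DataFrame, frac: float = 0.8,
                    ) -> tuple[str, int, int] | None:
    """Merge the top window with overlapping near-top windows into the peak.

    SNPs in tight linkage with the causal one produce a plateau of
    near-equal windows rather than a single spike; the peak region is the
    maximal run of windows on the top window's chromosome that overlap it
    (transitively) and score at least ``frac`` of the top mean delta.
    """
    if profile.empty:
        return None
    top = profile.iloc[0]
    near = profile[(profile["chrom"] == top["chrom"])
                   & (profile["mean_delta"] >= frac * top["mean_delta"])]
    spans = iv.merge(list(zip(near["start"], near["end"])))
    for s, e in spans:
        if s <= top["start"] and top["end"] <= e:
            return str(top["chrom"]), int(s), int(e)
    return str(top["chrom"]), int(top["start"]), int(top["end"])


# ---------------------------------------------------------------------------
# CAPS markers

def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _site_count(seq: str, motif: str, around: int, span: int) -> int:
    """Motif occurrences (either strand) overlapping position ``around``."""
    lo = max(0, around - span + 1)
    hi = min(len(seq), around + span)
    region = seq[lo:hi]
    count = 0
    for m in {motif, _revcomp(motif)}:
        count += sum(1 for i in range(len(region) - len(m) + 1)
                     if region[i:i + len(m)] == m)
    return count


def caps_check(flanking_seq: str, snp: tuple[int, str, str],
               enzyme_motif: str) -> str:
    """Classify a SNP as creating/destroying a restriction site.

    Compares the number of motif occurrences (on either strand) overlapping
    the SNP position between the reference and alternate sequence.
    """
    offset, ref, alt = snp
    seq = flanking_seq.upper()
    motif = enzyme_motif.upper()
    if not set(motif) <= set("ACGT"):
        raise ValueError("enzyme motif must be over {A,C,G,T}")
    if not 0 <= offset < len(seq):
        raise ValueError("SNP offset outside the flanking sequence")
    if seq[offset] != ref.upper():
        raise ValueError(f"reference base mismatch at offset {offset}: "
                         f"sequence has {seq[offset]}, SNP says {ref}")
    alt_seq = seq[:offset] + alt.upper() + seq[offset + 1:]
    span = len(motif)
    n_ref = _site_count(seq, motif, offset, span)
    n_alt = _site_count(alt_seq, motif, offset, span)
    if n_alt > n_ref:
        return "creates_site"
    if n_alt < n_ref:
        return "destroys_site"
    return "uninformative"
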