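"""Per-cytosine methylation call handling.

Calls live in a pandas DataFrame with columns ``chrom, pos, strand, context,
n_meth, n_total`` — one row per cytosine per strand. Coordinates are 0-based
throughout; dialects that use 1-based positions are converted at the file
boundary.

Context assignment follows the standard plant trinucleotide classification:
reading 5'->3' on the cytosine's own strand, CG if the next base is G, CHG if
the next two bases are H (A/C/T) then G, CHH if both are H. A cytosine whose
two downstream bases contain N or run off the chromosome end is
"undetermined" and excluded from all windowed summaries.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CALL_COLUMNS",
    "CONTEXTS",
    "classify_contexts",
    "filter_min_coverage",
    "to_signed_track",
    "read_calls",
    "write_calls",
    "write_bedgraph",
    "read_bedgraph",
]

CALL_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_total"]
CONTEXTS = ("CG", "CHG", "CHH")

_COMPLEMENT = {65: 84, 84: 65, 67: 71, 71: 67, 78: 78}  # A<->T, C<->G, N->N


def classify_contexts(sequence: str, chrom: str = "seq") -> pd.DataFrame:
    """Assign a (strand, context) to every cytosine on both strands.

    Returns a DataFrame with columns ``chrom, pos, strand, context`` sorted by
    position; context is one of CG/CHG/CHH or "undetermined".

    Raises ``ValueError`` naming the offset of the first non-IUPAC character.
    """

    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8).copy()
    valid = np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if not valid.all():
        offset = int(np.flatnonzero(~valid)[0])
        raise ValueError(
            f"non-IUPAC character {sequence[offset]!r} at offset {offset}"
        )

    n = arr.size
    comp = np.full(256, 78, dtype=np.uint8)
    for k, v in _COMPLEMENT.items():
        comp[k] = v

    # pad with N so downstream lookups never run off the array
    padded = np.concatenate([np.full(2, 78, dtype=np.uint8), arr,
                             np.full(2, 78, dtype=np.uint8)])

    records = []
    for strand, base in (("+", 67), ("-", 71)):  # C on plus, G on minus
        pos = np.flatnonzero(arr == base)
        if strand == "+":
            b1 = padded[pos + 3]
            b2 = padded[pos + 4]
        else:
            b1 = comp[padded[pos + 1]]
            b2 = comp[padded[pos + 0]]
        is_h1 = np.isin(b1, np.frombuffer(b"ACT", dtype=np.uint8))
        is_h2 = np.isin(b2, np.frombuffer(b"ACT", dtype=np.uint8))
        context = np.full(pos.size, "undetermined", dtype=object)
        context[b1 == 71] = "CG"
        context[is_h1 & (b2 == 71)] = "CHG"
        context[is_h1 & is_h2] = "CHH"
        records.append(pd.DataFrame({
            "chrom": chrom, "pos": pos, "strand": strand, "context": context,
        }))

    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)


def filter_min_coverage(calls: pd.DataFrame, min_reads: int = 3) -> pd.DataFrame:
    """Retain calls at positions covered by at least ``min_reads`` reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return calls[calls["n_total"] >= min_reads].reset_index(drop=True)


def to_signed_track(calls: pd.DataFrame) -> pd.DataFrame:
    """Scale methylation ratios to [0, 1] and negate minus-strand values.

    Plus-strand values are n_meth/n_total in [0, 1]; minus-strand values are
    multiplied by -1, so the sign encodes the reference strand.
    """
    if (calls["n_total"] <= 0).any():
        raise ValueError("calls must be coverage-filtered (n_total > 0)")
    value = calls["n_meth"].to_numpy(float) / calls["n_total"].to_numpy(float)
    value = np.where(calls["strand"].to_numpy() == "-", -value, value)
    return pd.DataFrame({
        "chrom": calls["chrom"].to_numpy(),
        "pos": calls["pos"].to_numpy(),
        "value": value,
    })


# ---------------------------------------------------------------------------
# call-table dialects

def write_calls(calls: pd.DataFrame, path, dialect: str = "cx") -> None:
    """Write a call table in the named dialect.

    ``cx``: Bismark-style cytosine report — chrom, 1-based position, strand,
    methylated count, unmethylated count, context, trinucleotide (written as
    "."). ``bedmethyl``: chrom, start, end, context, valid coverage, strand,
    percent methylated.
    """
    if dialect == "cx":
        df = pd.DataFrame({
            "chrom": calls["chrom"],
            "pos": calls["pos"] + 1,
            "strand": calls["strand"],
            "n_meth": calls["n_meth"],
            "n_unmeth": calls["n_total"] - calls["n_meth"],
            "context": calls["context"],
            "trinucleotide": ".",
        })
    elif dialect == "bedmethyl":
        pct = 100.0 * calls["n_meth"] / calls["n_total"]
        df = pd.DataFrame({
            "chrom": calls["chrom"],
            "start": calls["pos"],
            "end": calls["pos"] + 1,
            "context": calls["context"],
            "coverage": calls["n_total"],
            "strand": calls["strand"],
            "percent": pct.round(2),
        })
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep="\t", header=False, index=False)


def _parse_error(path, lineno: int, line: str) -> ValueError:
    return ValueError(f"{path}: malformed line {lineno}: {line.rstrip()!r}")


def read_calls(path, dialect: str = "cx") -> pd.DataFrame:
    """Read a call table written in the named dialect (see write_calls)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if dialect == "cx":
                    chrom, pos1, strand, nm, nu = fields[:5]
                    context = fields[5] if len(fields) > 5 else "undetermined"
                    rows.append((chrom, int(pos1) - 1, strand, context,
                                 int(nm), int(nm) + int(nu)))
                elif dialect == "bedmethyl":
                    chrom, start, _end, context, cov, strand, pct = fields[:7]
                    n_total = int(cov)
                    n_meth = int(np.floor(float(pct) / 100.0 * n_total + 0.5))
                    rows.append((chrom, int(start), strand, context,
                                 n_meth, n_total))
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except (ValueError, IndexError) as exc:
                if "unknown dialect" in str(exc):
                    raise
                raise _parse_error(path, lineno, line) from exc
    out = pd.DataFrame(rows, columns=CALL_COLUMNS)
    if (out["n_meth"] > out["n_total"]).any():
        raise ValueError(f"{path}: methylated count exceeds coverage")
    return out


# ---------------------------------------------------------------------------
# bedGraph

def write_bedgraph(track: pd.DataFrame, path,
                   columns: Iterable[str] = ("chrom", "start", "end", "value"),
                   ) -> None:
    track.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False,
                                       float_format="%.6g")


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df
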