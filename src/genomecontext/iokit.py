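"""Domain types and file dialects shared by all genome-context modules.

The package works from three plain-text inputs:

* a homology table: one row per (target gene, reference organism, reference
  gene) BLAST-style hit with an E-value and the percent of the target gene's
  sequence covered by the match;
* genome annotations (GFF3 ``gene`` features or an internal TSV dialect)
  giving each gene's replicon, coordinates and strand, plus replicon length
  and circularity;
* a gold-standard table of labeled gene pairs.

Everything downstream consumes the in-memory types defined here; no other
module re-reads files.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "HomologyHit",
    "GeneRecord",
    "RepliconInfo",
    "ProfileMatrix",
    "ScoreMatrix",
    "PairLabel",
    "read_homology_table",
    "read_annotation",
    "write_annotation",
    "write_homology_table",
    "write_pair_scores",
    "read_pair_scores",
    "read_pair_labels",
    "write_pair_labels",
]

#: Out-of-band sentinel for pairs a method cannot score (restricted
#: coverage, the diagonal, or absent homology evidence).  NaN never collides
#: with a real score and propagates safely through arithmetic.
MISSING = float("nan")


@dataclass(frozen=True)
class HomologyHit:
    """A single best hit of a target gene against a reference gene."""

    target_gene: str
    organism: str
    ref_gene: str
    e_value: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError(f"negative e_value for {self.target_gene}: {self.e_value}")
        if not 0.0 <= self.coverage_pct <= 100.0:
            raise ValueError(
                f"coverage_pct outside [0, 100] for {self.target_gene}: {self.coverage_pct}"
            )


@dataclass(frozen=True)
class GeneRecord:
    """One gene of an annotated genome; coordinates are 1-based inclusive.

    ``rank`` is the 1-based position of the gene along its replicon by
    ascending start coordinate (ties broken by gene id); gene-rank distance,
    not base distance, feeds the gene-neighbor method.
    """

    gene_id: str
    organism: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start > end for gene {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.gene_id}")


@dataclass(frozen=True)
class RepliconInfo:
    replicon_id: str
    organism: str
    length_bases: int
    circular: bool = True


@dataclass(frozen=True)
class PairLabel:
    gene_a: str
    gene_b: str
    label: int  # 1 positive, 0 negative

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair in gold standard: {self.gene_a}")


@dataclass
class ProfileMatrix:
    """Phylogenetic profiles: genes x organisms binary matrix.

    Rows are gene profiles; columns are organism profiles.
    """

    genes: list[str]
    organisms: list[str]
    bits: np.ndarray

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (len(self.genes), len(self.organisms)):
            raise ValueError("profile matrix shape mismatch")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")

    def row(self, gene: str) -> np.ndarray:
        return self.bits[self.genes.index(gene)]


@dataclass
class ScoreMatrix:
    """Symmetric gene x gene score matrix, oriented higher = more related.

    Raw p-values and distances are negated before storage so that every
    published matrix obeys a single orientation contract.  The diagonal and
    unscorable pairs carry the NaN sentinel.  ``restricted`` marks matrices
    from restricted-coverage methods (gene cluster, gene fusion), whose
    sentinel semantically means "worst possible score" and which must not be
    row-normalized.
    """

    genes: list[str]
    values: np.ndarray
    restricted: bool = False
    method: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genes)
        if self.values.shape != (n, n):
            raise ValueError("score matrix shape mismatch")

    @classmethod
    def empty(cls, genes: Sequence[str], restricted: bool = False,
              method: str = "") -> "ScoreMatrix":
        n = len(genes)
        return cls(list(genes), np.full((n, n), MISSING), restricted, method)

    def copy(self) -> "ScoreMatrix":
        return ScoreMatrix(list(self.genes), self.values.copy(),
                           self.restricted, self.method)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.genes.index(a), self.genes.index(b)])

    def set_pair(self, a: str, b: str, value: float) -> None:
        i, j = self.genes.index(a), self.genes.index(b)
        self.values[i, j] = value
        self.values[j, i] = value

    def pair_series(self) -> pd.Series:
        """Long-format view: one entry per unordered pair (a < b)."""
        idx, vals = [], []
        for i in range(len(self.genes)):
            for j in range(i + 1, len(self.genes)):
                a, b = sorted((self.genes[i], self.genes[j]))
                idx.append((a, b))
                vals.append(self.values[i, j])
        return pd.Series(vals, index=pd.MultiIndex.from_tuples(idx))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_HOM_COLS = ["target_gene", "organism", "ref_gene", "e_value", "coverage_pct"]


def read_homology_table(path, e_cap: float = float("inf")) -> list[HomologyHit]:
    """Read a homology table, dropping hits with ``e_value > e_cap`` and
    collapsing duplicate (target, organism, ref) rows to the best hit
    (minimum E-value, maximum coverage)."""
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in _HOM_COLS[:3]})
    missing = set(_HOM_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"homology table missing columns: {sorted(missing)}")
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        if row.e_value < 0 or not (0 <= row.coverage_pct <= 100):
            raise ValueError(f"malformed homology row at line {line_no}")
    df = df[df["e_value"] <= e_cap]
    collapsed = df.groupby(_HOM_COLS[:3], as_index=False).agg(
        e_value=("e_value", "min"), coverage_pct=("coverage_pct", "max")
    )
    return [HomologyHit(*row) for row in collapsed.itertuples(index=False)]


def write_homology_table(hits: Iterable[HomologyHit], path) -> None:
    df = pd.DataFrame(
        [(h.target_gene, h.organism, h.ref_gene, h.e_value, h.coverage_pct)
         for h in hits],
        columns=_HOM_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def _assign_ranks(genes: list[GeneRecord]) -> list[GeneRecord]:
    """Rank genes per replicon by ascending start; ties by gene id."""
    out: list[GeneRecord] = []
    by_rep: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_rep.setdefault((g.organism, g.replicon_id), []).append(g)
    for recs in by_rep.values():
        recs.sort(key=lambda g: (g.start, g.gene_id))
        for rank, g in enumerate(recs, start=1):
            out.append(GeneRecord(g.gene_id, g.organism, g.replicon_id,
                                  g.start, g.end, g.strand, rank))
    return out


_ANN_COLS = ["gene_id", "organism", "replicon_id", "start", "end", "strand"]


def read_annotation(path, dialect: str = "tsv") -> tuple[list[GeneRecord], list[RepliconInfo]]:
    """Read genome annotation (internal TSV or GFF3 ``gene`` features).

    The TSV dialect carries replicon metadata on ``#replicon`` comment lines:
    ``#replicon <id> <organism> <length> <circular|linear>``.  GFF3 replicon
    length comes from ``##sequence-region`` pragmas (circular assumed).
    """
    genes: list[GeneRecord] = []
    replicons: list[RepliconInfo] = []
    if dialect == "tsv":
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#replicon"):
                    _, rep_id, org, length, topo = line.split("\t")
                    replicons.append(RepliconInfo(rep_id, org, int(length),
                                                  topo == "circular"))
                    continue
                if line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 6:
                    raise ValueError(f"malformed annotation row at line {line_no}")
                gid, org, rep, start, end, strand = parts
                if strand not in ("+", "-"):
                    raise ValueError(f"missing/bad strand at line {line_no}")
                genes.append(GeneRecord(gid, org, rep, int(start), int(end), strand))
    elif dialect == "gff3":
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if line.startswith("##sequence-region"):
                    _, rep_id, _start, end = line.split()
                    replicons.append(RepliconInfo(rep_id, "", int(end), True))
                    continue
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) != 9:
                    raise ValueError(f"malformed GFF3 row at line {line_no}")
                seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cols
                if ftype != "gene":
                    continue
                if strand not in ("+", "-"):
                    raise ValueError(f"missing strand at line {line_no}")
                attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
                gid = attr.get("ID") or attr.get("Name")
                org = attr.get("organism", "")
                genes.append(GeneRecord(gid, org, seqid, int(start), int(end), strand))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return _assign_ranks(genes), replicons


def write_annotation(genes: Iterable[GeneRecord],
                     replicons: Iterable[RepliconInfo], path) -> None:
    with open(path, "w") as fh:
        for r in replicons:
            topo = "circular" if r.circular else "linear"
            fh.write(f"#replicon\t{r.replicon_id}\t{r.organism}\t{r.length_bases}\t{topo}\n")
        for g in sorted(genes, key=lambda g: (g.organism, g.replicon_id, g.start, g.gene_id)):
            fh.write(f"{g.gene_id}\t{g.organism}\t{g.replicon_id}\t{g.start}\t{g.end}\t{g.strand}\n")


def write_pair_scores(matrix: ScoreMatrix, path, emit_missing: bool = False) -> None:
    """Write a score matrix as long-format TSV ``gene_a gene_b score`` with
    gene_a < gene_b; missing pairs are omitted unless ``emit_missing``, in
    which case they carry the literal ``NA``."""
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\n")
        for (a, b), v in matrix.pair_series().items():
            if np.isnan(v):
                if emit_missing:
                    fh.write(f"{a}\t{b}\tNA\n")
            else:
                fh.write(f"{a}\t{b}\t{float(v)!r}\n")


def read_pair_scores(path, genes: Sequence[str] | None = None,
                     restricted: bool = False) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str},
                     na_values=["NA"])
    if genes is None:
        genes = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    m = ScoreMatrix.empty(genes, restricted=restricted)
    for row in df.itertuples(index=False):
        if not np.isnan(row.score):
            m.set_pair(row.gene_a, row.gene_b, float(row.score))
    return m


def read_pair_labels(path) -> list[PairLabel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    seen: dict[frozenset, int] = {}
    out: list[PairLabel] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        lab = 1 if str(row.label) in ("1", "positive") else 0
        pl = PairLabel(row.gene_a, row.gene_b, lab)  # raises on self-pair
        key = frozenset((row.gene_a, row.gene_b))
        if key in seen:
            raise ValueError(f"duplicate pair in gold standard at line {line_no}")
        seen[key] = lab
        out.append(pl)
    return out


def write_pair_labels(labels: Iterable[PairLabel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tlabel\n")
        for p in labels:
            a, b = sorted((p.gene_a, p.gene_b))
            fh.write(f"{a}\t{b}\t{'positive' if p.label else 'negative'}\n")
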