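"""Reference tag index, bounded-mismatch tag mapping, and coverage.

Every CATG occurrence with at least 17 following bases, on either strand of
every unigene, defines one indexed 21-bp reference tag.  Clean tags are then
assigned at the minimal Hamming distance not exceeding ``max_mismatch``
(default 1, the pipeline's mapping rule); the CATG anchor is enzymatically
fixed, so the mismatch neighbourhood enumerates only the 17 variable
positions.  A tag whose minimal-distance hits name exactly one gene counts to
that gene (unique match); hits naming several genes are multi-position and
count to no gene.  The mapping ledger satisfies:

    total_mapped == perfect_match + mismatch_match
    total_mapped == unique_match + multi_position
    total_clean  == total_mapped + unmapped
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simdata import ANCHOR, TAG_LENGTH
from .tagproc import CleanTagTable


class TagSite(NamedTuple):
    gene: str
    strand: str          # '+' or '-', relative to the stored sequence
    site_rank: int       # 1 = closest to the 3' end of that strand
    fwd_start: int       # footprint start in stored (forward) coordinates


@dataclass
class ReferenceTagIndex:
    """Map from 21-bp tag sequence to its source sites in the unigene set."""

    sites: dict[str, list[TagSite]]
    gene_lengths: dict[str, int]
    ambiguous: set[str] = field(default_factory=set)

    def genes_of(self, tag: str) -> set[str]:
        return {s.gene for s in self.sites.get(tag, ())}

    def __len__(self) -> int:
        return len(self.sites)


def build_index(reference: "str | Iterable[SeqRecord]") -> ReferenceTagIndex:
    """Index every CATG+17 tag of every unigene, both strands.

    ``reference`` is a FASTA path or an iterable of SeqRecords.  Tags spanning
    an N are skipped; duplicate sequence ids are rejected.
    """
    if isinstance(reference, (str, bytes)) or hasattr(reference, "__fspath__"):
        records: Iterable[SeqRecord] = SeqIO.parse(str(reference), "fasta")
    else:
        records = reference
    sites: dict[str, list[TagSite]] = {}
    lengths: dict[str, int] = {}
    for rec in records:
        if rec.id in lengths:
            raise ValueError(f"duplicate sequence id in reference: {rec.id!r}")
        fwd = str(rec.seq).upper()
        L = len(fwd)
        lengths[rec.id] = L
        for strand, s in (("+", fwd), ("-", str(Seq(fwd).reverse_complement()))):
            starts = []
            pos = s.find(ANCHOR)
            while pos != -1:
                if pos + TAG_LENGTH <= L:
                    starts.append(pos)
                pos = s.find(ANCHOR, pos + 1)
            # rank 1 = 3'-most on this strand
            for rank, p in enumerate(sorted(starts, reverse=True), start=1):
                tag = s[p:p + TAG_LENGTH]
                if "N" in tag:
                    continue
                fwd_start = p if strand == "+" else L - (p + TAG_LENGTH)
                sites.setdefault(tag, []).append(
                    TagSite(rec.id, strand, rank, fwd_start))
    index = ReferenceTagIndex(sites=sites, gene_lengths=lengths)
    index.ambiguous = {t for t, ss in sites.items()
                       if len({s.gene for s in ss}) > 1}
    return index


@dataclass
class MappingLedger:
    total_clean: int = 0
    total_mapped: int = 0
    perfect_match: int = 0
    mismatch_match: int = 0
    unique_match: int = 0
    multi_position: int = 0
    unmapped: int = 0

    def validate(self) -> None:
        if self.total_mapped != self.perfect_match + self.mismatch_match:
            raise ValueError("mapped != perfect + mismatch")
        if self.total_mapped != self.unique_match + self.multi_position:
            raise ValueError("mapped != unique + multi_position")
        if self.total_clean != self.total_mapped + self.unmapped:
            raise ValueError("clean != mapped + unmapped")

    def as_dict(self) -> dict[str, int]:
        return {k: getattr(self, k) for k in
                ("total_clean", "total_mapped", "perfect_match",
                 "mismatch_match", "unique_match", "multi_position",
                 "unmapped")}


def _neighbours(tag: str, distance: int):
    """All sequences at exactly ``distance`` substitutions from ``tag``,
    holding the 4-bp anchor fixed."""
    variable = range(len(ANCHOR), TAG_LENGTH)
    for positions in combinations(variable, distance):
        alts = [[b for b in "ACGT" if b != tag[p]] for p in positions]
        def rec(i, current):
            if i == len(positions):
                yield "".join(current)
                return
            p = positions[i]
            for b in alts[i]:
                current[p] = b
                yield from rec(i + 1, current)
            current[p] = tag[p]
        yield from rec(0, list(tag))


class MappingResult(NamedTuple):
    counts: pd.Series            # per-gene unique-match read counts
    ledger: MappingLedger
    placements: pd.DataFrame     # gene, strand, start, copies (unique matches)


def map_tags(table: CleanTagTable, index: ReferenceTagIndex,
             max_mismatch: int = 1) -> MappingResult:
    """Assign each distinct clean tag at minimal mismatch distance <= max_mismatch."""
    if max_mismatch not in (0, 1, 2):
        raise ValueError("max_mismatch must be 0, 1 or 2")
    ledger = MappingLedger()
    gene_counts: dict[str, int] = {g: 0 for g in index.gene_lengths}
    placements: list[tuple[str, str, int, int]] = []
    for tag, copies in table.counts.items():
        ledger.total_clean += copies
        hits: list[TagSite] = []
        distance = -1
        for d in range(max_mismatch + 1):
            if d == 0:
                cands = index.sites.get(tag)
                if cands:
                    hits = list(cands)
            else:
                for nb in _neighbours(tag, d):
                    cands = index.sites.get(nb)
                    if cands:
                        hits.extend(cands)
            if hits:
                distance = d
                break
        if distance < 0:
            ledger.unmapped += copies
            continue
        ledger.total_mapped += copies
        if distance == 0:
            ledger.perfect_match += copies
        else:
            ledger.mismatch_match += copies
        genes = {h.gene for h in hits}
        if len(genes) == 1:
            gene = genes.pop()
            ledger.unique_match += copies
            gene_counts[gene] += copies
            for h in hits:
                placements.append((h.gene, h.strand, h.fwd_start, copies))
        else:
            ledger.multi_position += copies
    ledger.validate()
    counts = pd.Series(gene_counts, name=table.library).sort_index()
    pl = pd.DataFrame(placements, columns=["gene", "strand", "start", "copies"])
    return MappingResult(counts=counts, ledger=ledger, placements=pl)


def coverage_profile(placements: pd.DataFrame,
                     gene_lengths: dict[str, int]) -> tuple[pd.Series, pd.Series]:
    """Fraction of each gene's bases under >= 1 mapped 21-bp tag footprint.

    Returns ``(coverage, histogram)`` where coverage is per-gene in [0, 1] and
    the histogram counts genes per decile bin.
    """
    cov = pd.Series(0.0, index=sorted(gene_lengths), name="coverage")
    if not placements.empty:
        for gene, grp in placements.groupby("gene"):
            L = gene_lengths[gene]
            ivals = sorted((max(0, int(s)), min(L, int(s) + TAG_LENGTH))
                           for s in grp["start"])
            covered, cur_lo, cur_hi = 0, *ivals[0]
            for lo, hi in ivals[1:]:
                if lo > cur_hi:
                    covered += cur_hi - cur_lo
                    cur_lo, cur_hi = lo, hi
                else:
                    cur_hi = max(cur_hi, hi)
            covered += cur_hi - cur_lo
            cov[gene] = covered / L
    edges = np.linspace(0.0, 1.0, 11)
    hist, _ = np.histogram(cov.to_numpy(), bins=edges)
    labels = [f"{edges[i]:.0%}-{edges[i+1]:.0%}" for i in range(10)]
    return cov, pd.Series(hist, index=labels, name="genes")


class ExpressionMatrix:
    """Gene x library raw unique-match counts with library totals and lengths.

    ``lib_totals`` are the per-library total clean tag counts (the
    normalisation denominators); ``mapped_totals`` default to column sums and
    are the RPKM denominators.
    """

    def __init__(self, counts: pd.DataFrame,
                 lib_totals: "dict[str, int] | None" = None,
                 gene_lengths: "dict[str, int] | None" = None):
        self.counts = counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.lib_totals = dict(lib_totals) if lib_totals else \
            {c: int(self.counts[c].sum()) for c in self.counts.columns}
        self.gene_lengths = dict(gene_lengths) if gene_lengths else {}
        for lib in self.counts.columns:
            if lib not in self.lib_totals:
                raise ValueError(f"missing library total for {lib!r}")

    @classmethod
    def from_mappings(cls, mappings: "dict[str, MappingResult]",
                      clean_totals: dict[str, int],
                      gene_lengths: dict[str, int]) -> "ExpressionMatrix":
        counts = pd.DataFrame({lib: m.counts for lib, m in mappings.items()})
        return cls(counts, lib_totals=clean_totals, gene_lengths=gene_lengths)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns)

    def tpm(self) -> pd.DataFrame:
        from .dge import normalize_tpm
        return pd.DataFrame({
            lib: normalize_tpm(self.counts[lib].to_numpy(), self.lib_totals[lib])
            for lib in self.counts.columns}, index=self.counts.index)

    def rpkm(self) -> pd.DataFrame:
        from .dge import normalize_rpkm
        lengths = pd.Series(self.gene_lengths).reindex(self.counts.index)
        return pd.DataFrame({
            lib: normalize_rpkm(self.counts[lib].to_numpy(),
                                lengths.to_numpy(),
                                int(self.counts[lib].sum()))
            for lib in self.counts.columns}, index=self.counts.index)

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, lib_totals=None, gene_lengths=None) -> "ExpressionMatrix":
        counts = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(counts, lib_totals=lib_totals, gene_lengths=gene_lengths)
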