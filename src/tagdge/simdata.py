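"""Synthetic unigene references and staged DGE tag libraries with known truth.

The generator emulates an NlaIII/MmeI tag-profiling experiment on a stem-swelling
time course: five libraries — a non-swelling mutant baseline plus four
developmental stages of a swelling strain — are drawn from one synthetic unigene
set.  Each transcript contributes copies of a single 21-bp tag (the NlaIII site
``CATG`` plus the 17 bases released by MmeI, taken at the 3'-most CATG site),
with per-base substitution errors, adaptor-only reads and N-containing reads
injected at configurable rates.  The ground truth (per-gene abundance, fold
trajectory, true per-library sampled counts) is returned alongside, so the
downstream cleaning/mapping/testing stages can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ANCHOR = "CATG"
TAG_LENGTH = 21
#: Synthetic Illumina-style adaptor used for adaptor-only reads. 21 bp, no CATG.
ADAPTOR_1 = "ACAGGTTCAGAGTTCTACAGT"

#: Library labels in biological order: mutant baseline, then the four stages.
DEFAULT_LIBRARIES = ("mutant", "stage1", "stage2", "stage3", "stage4")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SyntheticDesign:
    """Parameters of one synthetic experiment.

    Defaults describe the benchmark conditions the pipeline is exercised under:
    1,000 unigenes, five libraries of 2x10^5 raw tags, 10% of genes truly
    changing with fold changes between 2 and 16 applied as a monotone
    trajectory over the four stages, and noise rates typical of an early
    Illumina tag run (0.1% per-base substitution, ~0.8% adaptor-only reads,
    rare N-containing reads).
    """

    n_genes: int = 1000
    gene_length_range: tuple[int, int] = (200, 2000)
    n_libraries: int = 5
    library_depth: int = 200_000
    de_fraction: float = 0.10
    fold_change_range: tuple[float, float] = (2.0, 16.0)
    error_rate: float = 0.001
    adaptor_only_rate: float = 0.008
    n_read_rate: float = 0.0001
    taggable_fraction: float = 0.95
    seed: int = 0
    library_names: tuple[str, ...] = DEFAULT_LIBRARIES

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        lo, hi = self.gene_length_range
        if hi < lo:
            raise ValueError(
                f"gene_length_range is degenerate: max {hi} < min {lo}"
            )
        if lo < 60 or hi > 20000:
            raise ValueError("gene_length_range must lie within [60, 20000]")
        for name in ("de_fraction", "error_rate", "adaptor_only_rate",
                     "n_read_rate", "taggable_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.fold_change_range[0] <= 1.0:
            raise ValueError("fold_change_range lower bound must be > 1")
        if self.fold_change_range[1] < self.fold_change_range[0]:
            raise ValueError("fold_change_range is degenerate (max < min)")
        if self.library_depth <= 0:
            raise ValueError("library_depth must be positive")
        if self.n_libraries != len(self.library_names):
            raise ValueError("library_names must match n_libraries")
        if self.adaptor_only_rate + self.n_read_rate > 1.0:
            raise ValueError("adaptor_only_rate + n_read_rate must be <= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        d["fold_change_range"] = list(self.fold_change_range)
        d["library_names"] = list(self.library_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticDesign":
        d = dict(d)
        for key in ("gene_length_range", "fold_change_range", "library_names"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def default_comparisons(libraries: Sequence[str] = DEFAULT_LIBRARIES) -> list[tuple[str, str]]:
    """The six staged (control, case) pairs: stages 2-4 against each baseline."""
    mutant, stage1 = libraries[0], libraries[1]
    cases = list(libraries[2:])
    return [(mutant, c) for c in cases] + [(stage1, c) for c in cases]


def comparison_label(control: str, case: str) -> str:
    return f"{case}_vs_{control}"


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_anchor(seq: np.ndarray, rng: np.random.Generator) -> None:
    """Destroy every CATG occurrence in-place (CATG is its own reverse
    complement, so this clears both strands)."""
    s = seq.tobytes()
    pos = s.find(b"CATG")
    while pos != -1:
        # C -> T cannot create a new CATG overlapping this window
        seq[pos] = b"T"
        s = seq.tobytes()
        pos = s.find(b"CATG")


def _last_tag_site(s: str) -> int:
    """3'-most CATG with >= 17 following bases, or -1."""
    return s.rfind(ANCHOR, 0, len(s) - TAG_LENGTH + len(ANCHOR))


def _assign_de(abundance: np.ndarray, taggable: np.ndarray, n_de: int,
               fold_range: tuple[float, float],
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pick the truly changing genes, their directions and fold changes.

    Directions are assigned in mass-balanced pairs.  Tags are sampled
    multinomially, i.e. as relative abundances; if the changing genes add net
    tag mass, every unchanged gene's relative abundance drifts (composition
    bias) and per-million normalisation misreads the drift as expression
    change, so the generator keeps the total mass ~constant: each
    down-regulated gene (losing mass a*(1-1/f)) is paired with an up-regulated
    gene of roughly a*(1-1/f)/(f-1) its abundance (gaining the same mass).

    Down-regulation is drawn from the well-expressed upper tier — a gene must
    be active in the baseline tissue before the time course can silence it —
    and the paired induced genes consequently start from moderate baselines.
    Returns ``(is_de, up, fold)`` arrays over all genes.
    """
    n = len(abundance)
    f_lo, f_hi = fold_range
    fold = np.exp(rng.uniform(np.log(f_lo), np.log(f_hi), size=n))
    is_de = np.zeros(n, dtype=bool)
    up = np.zeros(n, dtype=bool)
    if n_de == 0:
        return is_de, up, fold
    cand = np.flatnonzero(taggable)
    cand = cand[np.argsort(abundance[cand], kind="stable")]
    if n_de > len(cand):
        raise ValueError("de_fraction requires more DE genes than tag-bearing genes")
    n_down = n_de // 2
    f_mid = math.sqrt(f_lo * f_hi)
    top = cand[-min(len(cand), max(3 * n_down, n_de)):]
    down = rng.choice(top, size=n_down, replace=False)
    is_de[down] = True
    avail = [g for g in cand if not is_de[g]]          # sorted by abundance
    avail_ab = [abundance[g] for g in avail]
    n_up = n_de - n_down
    targets = [abundance[g] * (1.0 - 1.0 / fold[g]) / (f_mid - 1.0)
               for g in sorted(down, key=lambda i: -abundance[i])]
    if n_up > n_down:                                   # odd n_de: one extra riser
        targets.append(float(np.median(targets)) if targets
                       else float(np.median(avail_ab)))
    for target in targets[:n_up]:
        j = int(np.searchsorted(avail_ab, target))
        j = min(max(j, 0), len(avail) - 1)
        if j > 0 and abs(avail_ab[j - 1] - target) < abs(avail_ab[j] - target):
            j -= 1
        g = avail.pop(j)
        avail_ab.pop(j)
        is_de[g] = True
        up[g] = True
    return is_de, up, fold


def make_reference(design: SyntheticDesign) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Generate the unigene reference and its ground-truth table.

    Returns ``(records, truth)``.  ``records`` are the unigene sequences as
    stored in the reference FASTA; a random half are stored reverse-complemented
    relative to the transcript (de novo unigenes have unknown orientation), in
    which case ``truth.strand`` is ``-`` and the transcript's tag appears on the
    minus strand of the stored sequence.

    ``truth`` has one row per gene: length, stored strand, the tag-generating
    site (3'-most CATG of the transcript) and its 21-bp tag, the baseline
    relative abundance (normalised to sum to 1), the signed fold change, the
    per-library fold multiplier columns ``mult_<lib>``, the exact per-comparison
    true log2 ratios ``true_log2_<label>`` and any-change flags ``de_<label>``.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_genes
    lo, hi = design.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    n_taggable = int(round(design.taggable_fraction * n))
    taggable = np.zeros(n, dtype=bool)
    taggable[rng.choice(n, size=n_taggable, replace=False)] = True
    flip = rng.random(n) < 0.5

    gene_ids = [f"gene{i:05d}" for i in range(n)]
    records: list[SeqRecord] = []
    tag_pos = np.full(n, -1)
    tag_seqs: list[str] = []
    for i in range(n):
        L = int(lengths[i])
        seq = _random_seq(rng, L)
        if taggable[i]:
            s = seq.tobytes().decode()
            pos = _last_tag_site(s)
            if pos == -1:
                # plant an anchor at a random valid position
                p = int(rng.integers(0, L - TAG_LENGTH + 1))
                seq[p:p + 4] = np.frombuffer(ANCHOR.encode(), dtype="S1")
                pos = _last_tag_site(seq.tobytes().decode())
            tag_pos[i] = pos
            tag_seqs.append(seq.tobytes().decode()[pos:pos + TAG_LENGTH])
        else:
            _scrub_anchor(seq, rng)
            tag_seqs.append("")
        transcript = seq.tobytes().decode()
        stored = str(Seq(transcript).reverse_complement()) if flip[i] else transcript
        records.append(SeqRecord(Seq(stored), id=gene_ids[i], description=""))

    abundance = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    abundance /= abundance.sum()

    # only tag-bearing genes can be observed; DE genes are taggable ones
    n_de = int(round(design.de_fraction * n))
    is_de, up, fold = _assign_de(abundance, taggable, n_de,
                                 design.fold_change_range, rng)
    signed_fold = np.where(is_de, np.where(up, fold, 1.0 / fold), 1.0)

    # trajectory over (mutant, stage1..stage4): 1, 1, f^(1/3), f^(2/3), f
    exponents = np.array([0.0, 0.0, 1 / 3, 2 / 3, 1.0])[: design.n_libraries]
    mult = signed_fold[:, None] ** exponents[None, :]

    truth = pd.DataFrame({
        "gene": gene_ids,
        "length": lengths,
        "taggable": taggable,
        "strand": np.where(flip, "-", "+"),
        "tag_pos": tag_pos,
        "tag": tag_seqs,
        "abundance": abundance,
        "is_de": is_de,
        "fold_change": signed_fold,
    }).set_index("gene")
    for j, lib in enumerate(design.library_names):
        truth[f"mult_{lib}"] = mult[:, j]
    for control, case in default_comparisons(design.library_names):
        lab = comparison_label(control, case)
        ratio = truth[f"mult_{case}"] / truth[f"mult_{control}"]
        truth[f"true_log2_{lab}"] = np.log2(ratio)
        truth[f"de_{lab}"] = ~np.isclose(ratio, 1.0)
    return records, truth


@dataclass
class SimulatedLibrary:
    """One raw tag library plus its ground truth."""

    library: str
    reads: list[str]
    true_counts: pd.Series  # per-gene sampled tag copies (before any noise)
    n_adaptor_only: int
    n_with_n: int


def simulate_library(
    truth: pd.DataFrame,
    library_index: int,
    design: SyntheticDesign,
) -> SimulatedLibrary:
    """Draw one library of ``design.library_depth`` raw 21-bp reads.

    Reads are split multinomially into adaptor-only, N-containing and tag reads;
    tag reads are drawn multinomially over tag-bearing genes with probability
    proportional to abundance x per-library fold multiplier, then subjected to
    iid per-base substitution at ``error_rate``.  The exact pre-noise per-gene
    copy numbers are returned: read conservation (sum of parts == depth) holds
    exactly.
    """
    if not 0 <= library_index < design.n_libraries:
        raise IndexError(
            f"library_index {library_index} out of range [0, {design.n_libraries})"
        )
    lib = design.library_names[library_index]
    rng = np.random.default_rng([design.seed, 1009 + library_index])
    depth = design.library_depth

    kinds = rng.multinomial(
        depth,
        [design.adaptor_only_rate, design.n_read_rate,
         1.0 - design.adaptor_only_rate - design.n_read_rate],
    )
    n_adaptor, n_nread, n_tags = (int(k) for k in kinds)

    tagged = truth[truth["taggable"]]
    if tagged.empty:
        raise ValueError("no tag-bearing genes in the reference")
    w = (tagged["abundance"] * tagged[f"mult_{lib}"]).to_numpy()
    probs = w / w.sum()
    counts = rng.multinomial(n_tags, probs)
    true_counts = pd.Series(0, index=truth.index, dtype=int, name=lib)
    true_counts.loc[tagged.index] = counts

    tag_arr = np.repeat(tagged["tag"].to_numpy(), counts)
    rng.shuffle(tag_arr)
    reads = _inject_errors(tag_arr, design.error_rate, rng)

    # N-containing reads: a real tag with one random base replaced by N
    if n_nread:
        src = rng.choice(tagged["tag"].to_numpy(), size=n_nread)
        for i in range(n_nread):
            p = int(rng.integers(0, TAG_LENGTH))
            t = src[i]
            reads.append(t[:p] + "N" + t[p + 1:])
    reads.extend([ADAPTOR_1] * n_adaptor)
    rng.shuffle(reads)
    return SimulatedLibrary(
        library=lib,
        reads=reads,
        true_counts=true_counts,
        n_adaptor_only=n_adaptor,
        n_with_n=n_nread,
    )


def _inject_errors(tags: np.ndarray, error_rate: float,
                   rng: np.random.Generator) -> list[str]:
    """Apply iid per-base substitutions to an array of tag strings."""
    reads = tags.tolist()
    if error_rate <= 0:
        return reads
    n_err = rng.binomial(TAG_LENGTH, error_rate, size=len(reads))
    for i in np.flatnonzero(n_err):
        t = list(reads[i])
        for p in rng.choice(TAG_LENGTH, size=n_err[i], replace=False):
            alts = [b for b in "ACGT" if b != t[p]]
            t[p] = alts[rng.integers(0, 3)]
        reads[i] = "".join(t)
    return reads


def make_annotation(
    truth: pd.DataFrame,
    n_terms: int = 20,
    annotated_fraction: float = 0.8,
    de_term_capture: float = 0.6,
    seed: int = 0,
    ontology: str = "GO",
) -> pd.DataFrame:
    """Synthetic gene -> term annotation with one term enriched for DE genes.

    ``term0000`` captures ``de_term_capture`` of the truly changing genes (plus
    background noise); the remaining terms are random decoys.  Returns a long
    table with columns ``gene``, ``term``, ``ontology``.
    """
    rng = np.random.default_rng([seed, 7919])
    genes = truth.index.to_numpy()
    annotated = genes[rng.random(len(genes)) < annotated_fraction]
    rows: list[tuple[str, str, str]] = []
    de_genes = truth.index[truth["is_de"]].intersection(annotated)
    picked = de_genes[rng.random(len(de_genes)) < de_term_capture]
    for g in picked:
        rows.append((g, "term0000", ontology))
    for t in range(1, n_terms):
        size = int(rng.integers(5, max(6, len(annotated) // 10)))
        for g in rng.choice(annotated, size=size, replace=False):
            rows.append((g, f"term{t:04d}", ontology))
    # make sure every annotated gene carries >= 1 term
    seen = {r[0] for r in rows}
    for g in annotated:
        if g not in seen:
            rows.append((g, f"term{int(rng.integers(1, n_terms)):04d}", ontology))
    return pd.DataFrame(rows, columns=["gene", "term", "ontology"])


# ---------------------------------------------------------------------------
# writers

def write_reference_fasta(records: Sequence[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{str(rec.seq)}\n")


def write_fastq(reads: Sequence[str], library: str, path) -> None:
    qual = "I" * TAG_LENGTH
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@{library}_{i}\n{r}\n+\n{qual[:len(r)]}\n")


def write_tag_counts(reads: Sequence[str], path) -> None:
    """Two-column tag/count TSV of the raw read multiset."""
    counts = pd.Series(reads).value_counts().sort_index()
    counts.rename_axis("tag").rename("count").to_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", float_format="%.10g")
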