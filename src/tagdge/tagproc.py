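"""Raw tag cleaning: from raw reads to a clean 21-bp tag table with a ledger.

Raw reads are classified in a fixed order — adaptor-only/empty, then
N-containing, then malformed (wrong length, missing CATG anchor, or non-ACGT
characters; counted as low quality) — and the survivors are tallied by distinct
tag sequence.  Distinct tags below the copy-number floor (default 2, i.e. tags
seen exactly once, the probable-sequencing-error rule) are then removed, their
reads booked as singleton_removed.  The ledger satisfies, on every input:

    raw == clean + adaptor_only + containing_N + low_quality + singleton_removed
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .simdata import ANCHOR, TAG_LENGTH

LEDGER_KEYS = ("raw", "clean", "adaptor_only", "containing_N",
               "low_quality", "singleton_removed")

_ACGT = frozenset("ACGT")


@dataclass
class CleanTagTable:
    """Distinct clean tags of one library with copy numbers and the read ledger."""

    library: str
    counts: dict[str, int]
    ledger: dict[str, int]

    def validate(self) -> None:
        lg = self.ledger
        parts = (lg["clean"] + lg["adaptor_only"] + lg["containing_N"]
                 + lg["low_quality"] + lg["singleton_removed"])
        if lg["raw"] != parts:
            raise ValueError(f"ledger does not conserve reads: raw={lg['raw']} parts={parts}")
        for tag, c in self.counts.items():
            if len(tag) != TAG_LENGTH or not tag.startswith(ANCHOR):
                raise ValueError(f"malformed clean tag {tag!r}")
            if c < 1:
                raise ValueError(f"non-positive copy number for {tag!r}")
        if sum(self.counts.values()) != lg["clean"]:
            raise ValueError("clean count does not match tag copy numbers")

    @property
    def total_clean(self) -> int:
        return self.ledger["clean"]

    def expand_reads(self) -> list[str]:
        """The clean reads as a flat multiset (for round-trip checks)."""
        return [t for t, c in self.counts.items() for _ in range(c)]


def filter_raw_tags(
    reads: Iterable[str],
    adaptors: Sequence[str] = (),
    tag_length: int = TAG_LENGTH,
    min_copy: int = 2,
    library: str = "lib",
) -> CleanTagTable:
    """Classify raw reads and build the clean tag table.

    ``min_copy=2`` removes copy-number-1 tags (the default error filter);
    ``min_copy=1`` keeps everything, which is appropriate for error-free input
    where singletons are real observations.
    """
    adaptor_set = set(adaptors)
    ledger = dict.fromkeys(LEDGER_KEYS, 0)
    tally: Counter[str] = Counter()
    for read in reads:
        ledger["raw"] += 1
        if read == "" or read in adaptor_set:
            ledger["adaptor_only"] += 1
        elif "N" in read:
            ledger["containing_N"] += 1
        elif (len(read) != tag_length or not read.startswith(ANCHOR)
              or not _ACGT.issuperset(read)):
            ledger["low_quality"] += 1
        else:
            tally[read] += 1
    counts: dict[str, int] = {}
    for tag in sorted(tally):
        c = tally[tag]
        if c < min_copy:
            ledger["singleton_removed"] += c
        else:
            counts[tag] = c
            ledger["clean"] += c
    table = CleanTagTable(library=library, counts=counts, ledger=ledger)
    table.validate()
    return table


def report_raw_components(table: CleanTagTable) -> pd.DataFrame:
    """Per-category raw-read accounting, counts and percentages of raw.

    One row per category in the layout of the raw-component summary table
    (clean reads first, then adaptor-only, N-containing, low-quality,
    singleton-removed)."""
    lg = table.ledger
    raw = lg["raw"]
    rows = []
    for key in ("clean", "adaptor_only", "containing_N", "low_quality",
                "singleton_removed"):
        pct = 100.0 * lg[key] / raw if raw else 0.0
        rows.append({"library": table.library, "category": key,
                     "reads": lg[key], "percent": round(pct, 2),
                     "formatted": f"{lg[key]}({pct:.2f}%)"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# io

def read_fastq_sequences(path) -> list[str]:
    from Bio import SeqIO
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def read_tag_counts(path) -> list[str]:
    """Expand a two-column tag/count TSV back into a read multiset."""
    df = pd.read_csv(path, sep="\t", dtype={"tag": str, "count": int})
    return [t for t, c in zip(df["tag"], df["count"]) for _ in range(c)]


def write_clean_table(table: CleanTagTable, tsv_path, ledger_path=None) -> None:
    pd.Series(table.counts, name="count").rename_axis("tag").to_csv(tsv_path, sep="\t")
    if ledger_path is not None:
        with open(ledger_path, "w") as fh:
            json.dump({"library": table.library, **table.ledger}, fh,
                      indent=2, sort_keys=True)
            fh.write("\n")


def read_clean_table(tsv_path, library: str = "lib",
                     ledger_path=None) -> CleanTagTable:
    df = pd.read_csv(tsv_path, sep="\t", dtype={"tag": str, "count": int})
    counts = dict(zip(df["tag"], df["count"]))
    if ledger_path is not None:
        with open(ledger_path) as fh:
            lg = json.load(fh)
        library = lg.pop("library", library)
        ledger = {k: int(lg[k]) for k in LEDGER_KEYS}
    else:
        total = sum(counts.values())
        ledger = dict.fromkeys(LEDGER_KEYS, 0)
        ledger.update(raw=total, clean=total)
    return CleanTagTable(library=library, counts=counts, ledger=ledger)
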