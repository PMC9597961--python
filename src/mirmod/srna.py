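"""Small-RNA tag processing.

Raw reads are collapsed to unique 18-25 nt tags with per-library counts,
classified against annotation sets (rRNA > tRNA > snoRNA > repeat, by
priority), and assigned to known miRNAs by Hamming distance (at most two
mismatches, same length). A Nussinov maximum-pairing recursion provides a
desk-scale stem-loop check for precursor candidates in place of
genome-based hairpin discovery tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LibraryDesign, SequenceRecord
from .seqs import CAN_PAIR, gc_fraction

ANNOTATION_PRIORITY = ("rRNA", "tRNA", "snoRNA", "repeat")
TAG_CLASSES = ("miRNA_known", "miRNA_candidate") + ANNOTATION_PRIORITY + ("unannotated",)

MIN_TAG_LEN = 18
MAX_TAG_LEN = 25

_VALID = frozenset("ACGU")


@dataclass
class TagTable:
    """Collapsed unique tags x libraries, with one annotation class per tag."""

    counts: pd.DataFrame                      # tags x library_ids, int
    annotation: pd.Series                     # tag -> class (TAG_CLASSES)
    assigned_mirna: pd.Series                 # tag -> reference miRNA id or ""
    discarded: dict[str, int] = field(default_factory=dict)  # accounting of dropped reads

    @property
    def tags(self) -> list[str]:
        return list(self.counts.index)

    def class_totals(self) -> pd.Series:
        """Number of unique tags per annotation class (a partition)."""
        return self.annotation.value_counts().reindex(TAG_CLASSES, fill_value=0)


def length_filter(reads_by_library: Mapping[str, Iterable[str]],
                  design: Sequence[LibraryDesign] | None = None,
                  min_len: int = MIN_TAG_LEN, max_len: int = MAX_TAG_LEN) -> TagTable:
    """Collapse reads to unique tags, discarding lengths outside [18, 25].

    Reads containing non-nucleotide characters are discarded and counted
    separately. Library columns follow ``design`` order when given.
    """
    lib_ids = ([d.library_id for d in design] if design is not None
               else list(reads_by_library))
    tag_counts: dict[str, dict[str, int]] = {}
    discarded = {"too_short": 0, "too_long": 0, "bad_characters": 0}
    for lib in lib_ids:
        for read in reads_by_library.get(lib, ()):
            seq = read.upper().replace("T", "U")
            if set(seq) - _VALID:
                discarded["bad_characters"] += 1
                continue
            if len(seq) < min_len:
                discarded["too_short"] += 1
                continue
            if len(seq) > max_len:
                discarded["too_long"] += 1
                continue
            tag_counts.setdefault(seq, {}).setdefault(lib, 0)
            tag_counts[seq][lib] += 1
    tags = sorted(tag_counts)
    counts = pd.DataFrame(
        [[tag_counts[t].get(lib, 0) for lib in lib_ids] for t in tags],
        index=tags, columns=lib_ids, dtype=int,
    )
    return TagTable(
        counts=counts,
        annotation=pd.Series("unannotated", index=tags, dtype=object),
        assigned_mirna=pd.Series("", index=tags, dtype=object),
        discarded=discarded,
    )


def classify_tags(table: TagTable,
                  annotation: Mapping[str, Sequence[SequenceRecord]]) -> TagTable:
    """Label tags matching annotation sequences, first class wins.

    A tag "matches" a class when it is an exact substring of any sequence of
    that class; classes are tried in the fixed priority order
    rRNA > tRNA > snoRNA > repeat. Tags already assigned to a miRNA class are
    left alone.
    """
    for tag in table.tags:
        if table.annotation[tag] not in ("unannotated",):
            continue
        for cls in ANNOTATION_PRIORITY:
            if any(tag in rec.seq for rec in annotation.get(cls, ())):
                table.annotation[tag] = cls
                break
    return table


def assign_known_mirnas(table: TagTable, reference_mirnas: Sequence[SequenceRecord],
                        max_mismatch: int = 2) -> TagTable:
    """Assign unannotated tags to known miRNAs by Hamming distance.

    Only same-length references are candidates (the mismatch rule counts
    substitutions, not indels). A tag is assigned to the minimum-distance
    reference with distance <= ``max_mismatch``; ties break to the
    lexicographically smallest reference id, so assignment is deterministic
    under any input ordering.
    """
    if not reference_mirnas:
        raise ValueError("reference miRNA set is empty")
    by_len: dict[int, list[SequenceRecord]] = {}
    for rec in sorted(reference_mirnas, key=lambda r: r.id):
        by_len.setdefault(len(rec.seq), []).append(rec)
    for tag in table.tags:
        if table.annotation[tag] != "unannotated":
            continue
        best_id, best_d = None, max_mismatch + 1
        for rec in by_len.get(len(tag), ()):
            d = sum(a != b for a, b in zip(tag, rec.seq))
            if d < best_d:
                best_id, best_d = rec.id, d
        if best_id is not None:
            table.annotation[tag] = "miRNA_known"
            table.assigned_mirna[tag] = best_id
    return table


def nussinov_pairs(seq: str | SequenceRecord, min_loop: int = 3) -> int:
    """Maximum number of non-crossing base pairs with hairpin loops >= min_loop.

    Standard O(n^3) recursion over {AU, UA, GC, CG, GU, UG} pairs. Sequences
    shorter than ``min_loop + 2`` cannot pair at all.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq.upper().replace("T", "U")
    n = len(s)
    if n < min_loop + 2:
        return 0
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        i_arr = np.arange(0, n - span)
        j_arr = i_arr + span
        for i, j in zip(i_arr, j_arr):
            best = dp[i + 1, j]  # i unpaired (also covered by bifurcation, kept for clarity)
            pairable = (s[i], s[j]) in CAN_PAIR
            if pairable:
                best = max(best, dp[i + 1, j - 1] + 1)
            # bifurcation: best split i..k / k+1..j
            k = np.arange(i, j)
            split = dp[i, k] + dp[k + 1, j]
            best = max(best, int(split.max()))
            dp[i, j] = best
    return int(dp[0, n - 1])


@dataclass(frozen=True)
class HairpinReport:
    """Outcome of the desk-scale stem-loop check for one precursor."""

    precursor_id: str
    max_pairs: int
    mirna_arm: str               # "5p", "3p", or "spans_loop"
    duplex_paired_fraction: float
    pairs_fraction: float
    length_in_window: bool       # inside the reported 100-120 nt concentration
    passed: bool


def hairpin_check(precursor: SequenceRecord, mirna: SequenceRecord,
                  min_pairs_fraction: float = 0.30,
                  min_duplex_paired: float = 0.60,
                  length_range: tuple[int, int] = (60, 300),
                  report_window: tuple[int, int] = (100, 120)) -> HairpinReport:
    """Check that a precursor folds into a stem-loop hosting the miRNA on one arm.

    Pass requires: Nussinov pairs / length >= ``min_pairs_fraction``, the
    miRNA:star duplex (read off the symmetric fold, position x pairing with
    position n+1-x) at least ``min_duplex_paired`` paired, the mature miRNA
    entirely on one side of the midpoint, and precursor length within
    ``length_range``. Thresholds are this package's surrogate defaults, not
    literature constants, and are configurable.
    """
    pre, mat = precursor.seq, mirna.seq
    n, L = len(pre), len(mat)
    first = pre.find(mat)
    if first == -1:
        raise ValueError(f"miRNA {mirna.id} not found in precursor {precursor.id}")
    unique = pre.find(mat, first + 1) == -1

    start = first + 1  # 1-based
    end = start + L - 1
    mid = (n + 1) / 2
    if end < mid:
        arm = "5p"
    elif start > mid:
        arm = "3p"
    else:
        arm = "spans_loop"

    paired = sum(
        (pre[x - 1], pre[n - x]) in CAN_PAIR  # partner of x is n + 1 - x
        for x in range(start, end + 1)
    )
    duplex_fraction = paired / L

    max_pairs = nussinov_pairs(pre)
    pairs_fraction = max_pairs / n
    in_range = length_range[0] <= n <= length_range[1]
    passed = (unique and arm != "spans_loop" and in_range
              and pairs_fraction >= min_pairs_fraction
              and duplex_fraction >= min_duplex_paired)
    return HairpinReport(
        precursor_id=precursor.id,
        max_pairs=max_pairs,
        mirna_arm=arm,
        duplex_paired_fraction=duplex_fraction,
        pairs_fraction=pairs_fraction,
        length_in_window=report_window[0] <= n <= report_window[1],
        passed=passed,
    )


def tag_stats(table: TagTable, weighted: bool = False) -> dict:
    """Descriptive statistics over the tag table.

    Returns the tag length histogram (fractions summing to 1), mean GC
    content, and per-class unique-tag totals. With ``weighted=True`` both the
    histogram and the GC mean are weighted by total read count per tag;
    the default treats each unique tag once.
    """
    if not len(table.counts):
        raise ValueError("tag table is empty")
    tags = table.tags
    weights = (table.counts.sum(axis=1).to_numpy(dtype=float) if weighted
               else np.ones(len(tags)))
    lengths = np.array([len(t) for t in tags])
    gc = np.array([gc_fraction(t) for t in tags])
    total = weights.sum()
    hist = {}
    for L in sorted(set(lengths)):
        hist[int(L)] = float(weights[lengths == L].sum() / total)
    return {
        "length_hist": hist,
        "gc_mean": float((gc * weights).sum() / total),
        "class_totals": table.class_totals().to_dict(),
        "n_tags": len(tags),
    }
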