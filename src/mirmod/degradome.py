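"""Degradome-guided miRNA target calling.

A miRNA:target duplex is scored with the plant-miRNA complementarity
penalty scheme used by classic PARE tools: mismatch 1.0, G:U wobble 0.5,
gap 2.0, all penalties doubled over the seed-proximal miRNA positions 2-13,
lower is better (0 = perfect complement). Candidate sites at or below a
score cutoff are validated against degradome 5'-end profiles: a cleavage
event requires at least one degradome read opposite miRNA position 10
(+/- a one-position window), and each event gets a CleaveLand-style
abundance category 0-4 relative to all signal on its transcript.

Alignment conventions
---------------------
The miRNA (5'->3', positions 1..L) pairs antiparallel with the target site,
so miRNA position i faces the (i-th from the 3' end) site base. At most one
gap is allowed: either one unpaired miRNA base ("gap in target", the site is
one base short) or one unpaired site base ("gap in miRNA", the site is one
base long, insertions only internal). An unpaired miRNA base at position i
is doubled when 2 <= i <= 13; an inserted site base between miRNA positions
i and i+1 is doubled when both flanks lie in the core, i.e. 2 <= i <= 12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DegradomeProfile, SequenceRecord
from .seqs import GU_PAIRS, WC_PAIRS, encode

MISMATCH = 1.0
GU_WOBBLE = 0.5
GAP = 2.0
CORE = (2, 13)          # seed-proximal miRNA positions with doubled penalties
DEFAULT_CUTOFF = 7.0
CLEAVAGE_MIRNA_POS = 10


class AlignmentError(ValueError):
    pass


def _pos_weight(i: int) -> float:
    return 2.0 if CORE[0] <= i <= CORE[1] else 1.0


def _pair_state(mirna_base: str, site_base: str) -> str:
    if (mirna_base, site_base) in WC_PAIRS:
        return "match"
    if (mirna_base, site_base) in GU_PAIRS:
        return "GU_wobble"
    return "mismatch"


_STATE_COST = {"match": 0.0, "GU_wobble": GU_WOBBLE, "mismatch": MISMATCH}


@dataclass(frozen=True)
class DuplexAlignment:
    """A scored miRNA:site duplex with its per-position states.

    ``states[i-1]`` is the state at miRNA position i (1-based from the 5'
    end); ``coord_map[i]`` is the 1-based transcript coordinate paired with
    miRNA position i, or None for an unpaired miRNA base. ``insertion``
    records an unpaired site base as (miRNA position i, transcript coord)
    meaning the base sits between miRNA positions i and i+1.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    score: float
    states: tuple[str, ...]
    coord_map: dict[int, int | None] = field(hash=False)
    insertion: tuple[int, int] | None = None

    @property
    def n_gaps(self) -> int:
        return int(self.insertion is not None) + sum(s == "gap_target" for s in self.states)

    def cleavage_candidates(self, window: int = 1) -> list[int]:
        """Transcript coordinates paired with miRNA positions 10 +/- window."""
        out = []
        for i in range(CLEAVAGE_MIRNA_POS - window, CLEAVAGE_MIRNA_POS + window + 1):
            coord = self.coord_map.get(i)
            if coord is not None:
                out.append(coord)
        return out


def duplex_score(mirna: SequenceRecord, site: SequenceRecord | str,
                 transcript_id: str = "", site_start: int = 1,
                 max_gaps: int = 1) -> DuplexAlignment:
    """Minimum-penalty antiparallel alignment of a miRNA to one site window.

    Enumerates every monotone alignment with at most ``max_gaps`` (0 or 1)
    gaps; ties prefer fewer gaps, then the gap closest to the site 5' end.
    """
    if max_gaps not in (0, 1):
        raise AlignmentError("only 0 or 1 gaps are supported")
    m = mirna.seq
    s = site.seq if isinstance(site, SequenceRecord) else site.upper().replace("T", "U")
    L, S = len(m), len(s)
    if abs(S - L) > max_gaps:
        raise AlignmentError(
            f"site length {S} incompatible with miRNA length {L} and max {max_gaps} gap(s)")

    best = None  # (score, n_gaps, gap_site_idx, layout)

    def consider(score, n_gaps, gap_site_idx, layout):
        nonlocal best
        key = (score, n_gaps, gap_site_idx)
        if best is None or key < (best[0], best[1], best[2]):
            best = (score, n_gaps, gap_site_idx, layout)

    if S == L:
        score = 0.0
        layout = []  # (mirna_pos, site_idx0) pairs
        for j in range(L):          # j = 0-based site index
            i = L - j               # miRNA position facing site base j
            st = _pair_state(m[i - 1], s[j])
            score += _STATE_COST[st] * _pos_weight(i)
            layout.append((i, j))
        consider(score, 0, -1, ("none", None, layout))
    elif S == L - 1:
        for i0 in range(1, L + 1):          # unpaired miRNA position
            j0 = L - i0                     # column index of the skipped base
            score = GAP * _pos_weight(i0)
            layout = []
            for j in range(L):
                if j == j0:
                    continue
                sj = j if j < j0 else j - 1
                i = L - j
                score += _STATE_COST[_pair_state(m[i - 1], s[sj])] * _pos_weight(i)
                layout.append((i, sj))
            consider(score, 1, j0, ("mirna_unpaired", i0, layout))
    else:  # S == L + 1, one internal inserted site base
        for i_ins in range(1, L):           # insertion between miRNA i_ins and i_ins+1
            j0 = L - i_ins                  # 0-based site index of the inserted base
            doubled = CORE[0] <= i_ins <= CORE[1] - 1
            score = GAP * (2.0 if doubled else 1.0)
            layout = []
            for j in range(L):
                sj = j if j < j0 else j + 1
                i = L - j
                score += _STATE_COST[_pair_state(m[i - 1], s[sj])] * _pos_weight(i)
                layout.append((i, sj))
            consider(score, 1, j0, ("site_inserted", i_ins, layout))

    score, n_gaps, _, (kind, gap_info, layout) = best
    states: list[str] = ["gap_target"] * L
    coord_map: dict[int, int | None] = {i: None for i in range(1, L + 1)}
    for i, sj in layout:
        states[i - 1] = _pair_state(m[i - 1], s[sj])
        coord_map[i] = site_start + sj
    insertion = None
    if kind == "site_inserted":
        insertion = (gap_info, site_start + (L - gap_info))
    return DuplexAlignment(
        mirna_id=mirna.id,
        transcript_id=transcript_id or (site.id if isinstance(site, SequenceRecord) else ""),
        site_start=site_start,
        site_end=site_start + S - 1,
        score=round(score, 10),
        states=tuple(states),
        coord_map=coord_map,
        insertion=insertion,
    )


def _cost_rows(mirna_seq: str, tx_codes: np.ndarray) -> np.ndarray:
    """M[j, p] = weighted penalty of site base t[p] facing reversed-miRNA column j."""
    L = len(mirna_seq)
    # cost0[a, b]: miRNA base a vs site base b (N always mismatches)
    cost0 = np.ones((5, 5))
    idx = {b: k for k, b in enumerate("ACGU")}
    for a, b in WC_PAIRS:
        cost0[idx[a], idx[b]] = 0.0
    for a, b in GU_PAIRS:
        cost0[idx[a], idx[b]] = GU_WOBBLE
    m_codes = encode(mirna_seq)[::-1]                       # column j = miRNA pos L - j
    weights = np.array([_pos_weight(L - j) for j in range(L)])
    return cost0[m_codes][:, tx_codes] * weights[:, None]


def scan_targets(mirna: SequenceRecord, transcript: SequenceRecord,
                 max_score: float = DEFAULT_CUTOFF, max_gaps: int = 1
                 ) -> list[DuplexAlignment]:
    """All non-redundant candidate sites with duplex score <= ``max_score``.

    Scores every window of the transcript exactly (the <= 1 gap optimum
    decomposes into prefix/suffix sums of the gapless penalty matrix, so the
    scan is vectorized without approximation), keeps the best alignment per
    site start, and returns hits sorted by score then position.
    """
    m, t = mirna.seq, transcript.seq
    L, T = len(m), len(t)
    if T < L:
        raise AlignmentError("transcript shorter than miRNA")
    M = _cost_rows(m, encode(t))                            # (L, T)

    n_starts = T - L + 1
    # A[k, s] = sum of columns j < k of the gapless alignment at start s
    A = np.zeros((L + 1, n_starts))
    for k in range(L):
        A[k + 1] = A[k] + M[k, k:k + n_starts]

    INF = np.inf
    best_score = A[L].copy()                                # gapless
    best_variant = np.zeros(n_starts, dtype=np.int8)        # 0 = gapless

    if max_gaps >= 1:
        # one unpaired miRNA base (site length L - 1); suffix realigns to start s-1
        tg = np.full(n_starts, INF)
        valid = np.arange(n_starts) >= 1
        for j0 in range(L):
            i0 = L - j0
            sc = np.full(n_starts, INF)
            sc[valid] = (A[j0, valid] + GAP * _pos_weight(i0)
                         + A[L, np.flatnonzero(valid) - 1]
                         - A[j0 + 1, np.flatnonzero(valid) - 1])
            tg = np.minimum(tg, sc)
        # one inserted site base (site length L + 1); suffix realigns to start s+1
        mg = np.full(n_starts, INF)
        valid_mg = np.arange(n_starts) <= n_starts - 2
        vs = np.flatnonzero(valid_mg)
        for i_ins in range(1, L):
            j0 = L - i_ins
            doubled = CORE[0] <= i_ins <= CORE[1] - 1
            sc = np.full(n_starts, INF)
            sc[vs] = (A[j0, vs] + GAP * (2.0 if doubled else 1.0)
                      + A[L, vs + 1] - A[j0, vs + 1])
            mg = np.minimum(mg, sc)
        for variant, scores in ((1, tg), (2, mg)):
            better = scores < best_score - 1e-12
            best_variant[better] = variant
            best_score = np.minimum(best_score, scores)

    hits = []
    for s in np.flatnonzero(best_score <= max_score + 1e-9):
        variant = best_variant[s]
        span = L + (0, -1, 1)[variant]
        site = t[s:s + span]
        aln = duplex_score(mirna, site, transcript_id=transcript.id,
                           site_start=int(s) + 1, max_gaps=max_gaps)
        hits.append(aln)
    hits.sort(key=lambda a: (a.score, a.site_start))
    return hits


@dataclass(frozen=True)
class CleavageEvent:
    """A degradome-supported cleavage of one target by one miRNA."""

    alignment: DuplexAlignment
    cleavage_pos: int
    degradome_count: int
    genotype: str
    category: int | None = None

    @property
    def pair_key(self) -> tuple[str, str, int]:
        return (self.alignment.mirna_id, self.alignment.transcript_id, self.cleavage_pos)


def call_cleavage(aln: DuplexAlignment, profile: DegradomeProfile,
                  window: int = 1, genotype: str = "") -> CleavageEvent | None:
    """Validate a duplex against a degradome profile.

    Looks at the transcript coordinates paired with miRNA positions
    10 - window .. 10 + window and records the position with the highest
    5'-end count (ties: closest to the canonical position-10 coordinate,
    then the smaller coordinate). Returns None when no read falls in the
    window.
    """
    if profile.transcript_id != aln.transcript_id:
        raise AlignmentError(
            f"profile {profile.transcript_id} does not match alignment on {aln.transcript_id}")
    candidates = aln.cleavage_candidates(window)
    if not candidates:
        return None
    canonical = aln.coord_map.get(CLEAVAGE_MIRNA_POS)
    if canonical is None:
        canonical = int(np.median(candidates))
    scored = [(profile.count_at(c), c) for c in candidates]
    count, pos = max(scored, key=lambda cp: (cp[0], -abs(cp[1] - canonical), -cp[1]))
    if count < 1:
        return None
    return CleavageEvent(alignment=aln, cleavage_pos=pos, degradome_count=count,
                         genotype=genotype)


def categorize(event: CleavageEvent, profile: DegradomeProfile) -> CleavageEvent:
    """CleaveLand-style abundance category.

    With c the count at the cleavage position, M the transcript-wide maximum
    and med the median of non-zero position counts (lower-middle median):
    4 if c == 1; 0 if c == M attained uniquely; 1 if c == M attained at
    several positions; 2 if med < c < M; 3 otherwise.
    """
    c = event.degradome_count
    counts = sorted(profile.positions.values())
    M = counts[-1]
    med = counts[(len(counts) - 1) // 2]
    if c == 1:
        cat = 4
    elif c == M:
        cat = 0 if counts.count(M) == 1 else 1
    elif c > med:
        cat = 2
    else:
        cat = 3
    return CleavageEvent(alignment=event.alignment, cleavage_pos=event.cleavage_pos,
                         degradome_count=c, genotype=event.genotype, category=cat)


def find_events(mirnas: Sequence[SequenceRecord], transcripts: Sequence[SequenceRecord],
                profiles: Mapping[str, DegradomeProfile], genotype: str,
                max_score: float = DEFAULT_CUTOFF, window: int = 1,
                max_gaps: int = 1) -> list[CleavageEvent]:
    """Scan all miRNA x transcript combinations against one genotype's profiles."""
    events = []
    for mirna in mirnas:
        for tx in transcripts:
            prof = profiles.get(tx.id)
            if prof is None:
                continue
            for aln in scan_targets(mirna, tx, max_score=max_score, max_gaps=max_gaps):
                ev = call_cleavage(aln, prof, window=window, genotype=genotype)
                if ev is not None:
                    events.append(categorize(ev, prof))
    return events


def pair_catalog(events_by_genotype: Mapping[str, Sequence[CleavageEvent]]) -> pd.DataFrame:
    """Unique (miRNA, transcript, cleavage position) pairs across genotypes.

    Different cleavage positions on the same miRNA-transcript combination
    are distinct pairs. Each pair is marked ST-specific, SS-specific, or
    shared; the three classes partition the catalog.
    """
    keys: dict[tuple, dict] = {}
    for genotype, events in events_by_genotype.items():
        for ev in events:
            rec = keys.setdefault(ev.pair_key, {"ST": False, "SS": False})
            rec[genotype] = True
    rows = []
    for (mirna_id, tx_id, pos) in sorted(keys):
        rec = keys[(mirna_id, tx_id, pos)]
        if rec["ST"] and rec["SS"]:
            occ = "shared"
        elif rec["ST"]:
            occ = "ST_specific"
        else:
            occ = "SS_specific"
        rows.append((mirna_id, tx_id, pos, rec["ST"], rec["SS"], occ))
    return pd.DataFrame(
        rows, columns=["mirna_id", "transcript_id", "cleavage_pos",
                       "in_ST", "in_SS", "occurrence"],
    )
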