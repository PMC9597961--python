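"""Coherent DEmiRNA-DEmRNA pairs and candidate salt-tolerance modules.

A *coherent pair* is a degradome-supported (miRNA, transcript, cleavage
position) pair whose miRNA and transcript are differentially expressed in
strictly opposite directions at the same (genotype, timepoint) contrast,
with the degradome evidence coming from that genotype's profile.

A coherent pair becomes a *candidate module* through the genotype contrast:
the pair is DE in genotype G while in the other genotype G' both partners
are either "little changed" (expressed but never significant at any
timepoint) or "not found" (below the expressed threshold in every G'
library). Pairs coherent in both genotypes are excluded. The four resulting
classes — DE in ST / flat in SS, DE in SS / flat in ST, ST-specific,
SS-specific — partition the candidates; the class label follows the miRNA's
situation in G' (specific when the miRNA itself is not found there).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import GENOTYPES, MODULE_CLASSES, TIMEPOINTS_H


@dataclass(frozen=True)
class CoherentPair:
    mirna_id: str
    transcript_id: str
    cleavage_pos: int
    genotype: str
    timepoint_h: float
    mirna_status: str   # "up" | "down"
    mrna_status: str    # the opposite of mirna_status

    def __post_init__(self) -> None:
        if {self.mirna_status, self.mrna_status} != {"up", "down"}:
            raise ValueError("coherent pair requires strictly opposite up/down statuses")

    @property
    def pair_key(self) -> tuple[str, str, int]:
        return (self.mirna_id, self.transcript_id, self.cleavage_pos)


@dataclass(frozen=True)
class CandidateModule:
    mirna_id: str
    transcript_id: str
    cleavage_pos: int
    klass: str
    de_genotype: str
    timepoints_h: tuple[float, ...]
    mirna_direction: str

    def __post_init__(self) -> None:
        if self.klass not in MODULE_CLASSES:
            raise ValueError(f"unknown module class {self.klass!r}")

    @property
    def pair_key(self) -> tuple[str, str, int]:
        return (self.mirna_id, self.transcript_id, self.cleavage_pos)


def _status_lookup(de_table: pd.DataFrame) -> dict[tuple, str]:
    return {
        (r.feature_id, r.genotype, r.timepoint_h): r.status
        for r in de_table.itertuples(index=False)
    }


def coherent_pairs(de_mirna: pd.DataFrame, de_mrna: pd.DataFrame,
                   pairs: pd.DataFrame, genotype: str, timepoint_h: float
                   ) -> list[CoherentPair]:
    """Degradome pairs whose partners are DE in opposite directions at one contrast.

    ``pairs`` is the catalog from :func:`mirmod.degradome.pair_catalog`; only
    pairs with degradome evidence in ``genotype`` qualify.
    """
    mir_status = _status_lookup(de_mirna)
    mrna_status = _status_lookup(de_mrna)
    t = float(timepoint_h)
    out = []
    for row in pairs.itertuples(index=False):
        if not getattr(row, f"in_{genotype}"):
            continue
        ms = mir_status.get((row.mirna_id, genotype, t))
        ts = mrna_status.get((row.transcript_id, genotype, t))
        if ms is None or ts is None:
            continue
        if {ms, ts} == {"up", "down"}:
            out.append(CoherentPair(row.mirna_id, row.transcript_id,
                                    int(row.cleavage_pos), genotype, t, ms, ts))
    return out


def _other(genotype: str) -> str:
    return GENOTYPES[1 - GENOTYPES.index(genotype)]


def _partner_contrast(feature_id: str, genotype: str, status: Mapping[tuple, str],
                      expressed: pd.DataFrame, label: str) -> str:
    """Situation of one feature in the non-DE genotype: 'flat', 'not_found' or 'de'."""
    if feature_id not in expressed.index:
        raise KeyError(f"{label} {feature_id!r} missing from expression-status table")
    if not bool(expressed.loc[feature_id, genotype]):
        return "not_found"
    for t in TIMEPOINTS_H:
        s = status.get((feature_id, genotype, t))
        if s is None:
            raise KeyError(f"{label} {feature_id!r} missing DE result at ({genotype}, {t} h)")
        if s in ("up", "down"):
            return "de"
    return "flat"


def classify_modules(coherent_by_genotype: Mapping[str, Sequence[CoherentPair]],
                     de_mirna: pd.DataFrame, de_mrna: pd.DataFrame,
                     expressed_mirna: pd.DataFrame, expressed_mrna: pd.DataFrame
                     ) -> list[CandidateModule]:
    """Apply the four-class genotype contrast to coherent pairs.

    For a pair coherent in genotype G (other genotype G'):

    * miRNA expressed in G' but never significant there -> "DE in G, flat in G'";
    * miRNA not expressed in G' -> "G-specific expression";
    * any significant call for the miRNA in G', or coherence in both
      genotypes, disqualifies the pair;
    * the target must mirror the condition (flat or not found in G').

    One module is emitted per unique pair key with supporting timepoints
    merged; the output is independent of input ordering.
    """
    mir_status = _status_lookup(de_mirna)
    mrna_status = _status_lookup(de_mrna)

    keys_per_genotype = {
        g: {p.pair_key for p in coherent_by_genotype.get(g, ())} for g in GENOTYPES
    }
    both = keys_per_genotype["ST"] & keys_per_genotype["SS"]

    merged: dict[tuple, dict] = {}
    for genotype in GENOTYPES:
        for pair in sorted(coherent_by_genotype.get(genotype, ()),
                           key=lambda p: (p.pair_key, p.timepoint_h)):
            if pair.pair_key in both:
                continue
            g_other = _other(genotype)
            mir_side = _partner_contrast(pair.mirna_id, g_other, mir_status,
                                         expressed_mirna, "miRNA")
            if mir_side == "de":
                continue
            mrna_side = _partner_contrast(pair.transcript_id, g_other, mrna_status,
                                          expressed_mrna, "transcript")
            if mrna_side == "de":
                continue
            if mir_side == "not_found":
                klass = f"{genotype}_specific_expression"
            else:
                klass = f"DE_in_{genotype}_flat_in_{g_other}"
            rec = merged.setdefault(pair.pair_key, {
                "klass": klass, "genotype": genotype,
                "timepoints": set(), "direction": pair.mirna_status,
            })
            rec["timepoints"].add(pair.timepoint_h)

    modules = []
    for (mirna_id, tx_id, pos) in sorted(merged):
        rec = merged[(mirna_id, tx_id, pos)]
        modules.append(CandidateModule(
            mirna_id=mirna_id, transcript_id=tx_id, cleavage_pos=pos,
            klass=rec["klass"], de_genotype=rec["genotype"],
            timepoints_h=tuple(sorted(rec["timepoints"])),
            mirna_direction=rec["direction"],
        ))
    return modules


def modules_frame(modules: Sequence[CandidateModule]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.mirna_id, m.transcript_id, m.cleavage_pos, m.klass, m.de_genotype,
             ";".join(f"{t:g}" for t in m.timepoints_h), m.mirna_direction)
            for m in modules
        ],
        columns=["mirna_id", "transcript_id", "cleavage_pos", "klass",
                 "de_genotype", "timepoints_h", "mirna_direction"],
    )


def module_report(modules: Sequence[CandidateModule],
                  coherent_by_genotype: Mapping[str, Sequence[CoherentPair]],
                  pairs: pd.DataFrame, de_mirna: pd.DataFrame) -> dict:
    """Summary counts with their internal identities.

    Class counts sum to the number of candidate modules; pair-catalog
    occurrence classes sum to the catalog size.
    """
    class_counts = {k: 0 for k in MODULE_CLASSES}
    for m in modules:
        class_counts[m.klass] += 1

    coherent_counts = {
        g: {f"{t:g}": sum(1 for p in coherent_by_genotype.get(g, ()) if p.timepoint_h == t)
            for t in TIMEPOINTS_H}
        for g in GENOTYPES
    }

    de_sig = de_mirna[de_mirna["status"].isin(["up", "down"])]
    demirna_counts = {
        g: {f"{t:g}": int(((de_sig["genotype"] == g)
                           & (de_sig["timepoint_h"] == t)).sum())
            for t in TIMEPOINTS_H}
        for g in GENOTYPES
    }
    demirna_unique = {
        g: int(de_sig.loc[de_sig["genotype"] == g, "feature_id"].nunique())
        for g in GENOTYPES
    }

    occ = pairs["occurrence"].value_counts().to_dict() if len(pairs) else {}
    catalog = {
        "total": int(len(pairs)),
        "ST_specific": int(occ.get("ST_specific", 0)),
        "SS_specific": int(occ.get("SS_specific", 0)),
        "shared": int(occ.get("shared", 0)),
    }
    assert catalog["total"] == (catalog["ST_specific"] + catalog["SS_specific"]
                                + catalog["shared"])
    assert sum(class_counts.values()) == len(modules)

    return {
        "n_candidate_modules": len(modules),
        "class_counts": class_counts,
        "coherent_pair_counts": coherent_counts,
        "demirna_counts": demirna_counts,
        "demirna_unique": demirna_unique,
        "pair_catalog": catalog,
    }
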