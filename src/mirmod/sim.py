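"""Synthetic tri-omics study generator.

Emits a complete simulated experiment mirroring the 2 genotypes (ST, SS) x
4 timepoints (0.5, 3, 8, 27 h) x 2 conditions (control, 150 mM NaCl) x
3 replicates = 48-library design:

* a miRNA catalog (lengths 18-25 nt, mode 21 nt, GC ~42.7%) with stem-loop
  precursors (100-120 nt) built so the hairpin surrogate check passes;
* a transcriptome in which each planted regulatory module carries a
  near-complementary miRNA target site at a recorded position;
* negative-binomial tag-count and transcript-count matrices with planted
  genotype-by-treatment effects (miRNA and target move in opposite
  directions);
* one pooled degradome 5'-end profile per genotype with planted cleavage
  peaks opposite miRNA position 10;
* a :class:`TruthSet` recording every planted module for recovery scoring.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    GENOTYPES,
    MODULE_CLASSES,
    TIMEPOINTS_H,
    DegradomeProfile,
    ExpressionMatrix,
    LibraryDesign,
    SequenceRecord,
    full_factorial_design,
    write_counts,
    write_degradome,
    write_design,
    write_fasta,
)
from .seqs import CAN_PAIR, WC_PAIRS, random_seq, revcomp

_DEFAULT_LENGTH_DIST = {
    18: 0.02, 19: 0.04, 20: 0.12, 21: 0.30,
    22: 0.14, 23: 0.10, 24: 0.22, 25: 0.06,
}


class ConfigError(ValueError):
    """A simulation configuration is internally inconsistent or infeasible."""


@dataclass
class SimConfig:
    """Tunable parameters of the synthetic study.

    Defaults reproduce the study layout (48 libraries) with sequence
    characteristics matching the reported miRNA catalog (length mode 21 nt,
    hairpins 100-120 nt, GC 42.74%). Count-noise and depth parameters have no
    counterpart in the source study and are this generator's own choices.
    """

    seed: int = 0
    n_mirna: int = 60
    n_transcripts: int = 300
    n_true_modules: int = 24
    mirna_length_dist: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_LENGTH_DIST))
    hairpin_length_range: tuple[int, int] = (100, 120)
    gc_target: float = 0.4274
    transcript_gc: float = 0.45
    transcript_length_range: tuple[int, int] = (800, 1200)
    effect_log2fc: float = 2.0
    dispersion: float = 0.05
    depth_per_library: int = 5_000_000
    mrna_depth_per_library: int = 2_000_000
    degradome_depth: int = 5_000
    degradome_peak_rate: float = 0.02
    background_cleavage_rate: float = 0.02
    module_class_mix: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    site_mismatches: int = 1
    # Baseline mean count per library for the "not found" genotype of
    # genotype-specific modules: effectively unexpressed, but nonzero so the
    # expressed filter (not the generator) makes the call.
    silent_baseline: float = 0.01
    min_planted_baseline: float = 200.0
    star_mutation_rate: float = 0.08
    depth_jitter: float = 0.0

    def validate(self) -> None:
        if self.n_mirna < 1 or self.n_transcripts < 1:
            raise ConfigError("need at least one miRNA and one transcript")
        if self.n_true_modules > min(self.n_mirna, self.n_transcripts):
            raise ConfigError(
                "n_true_modules exceeds available distinct miRNAs/transcripts")
        total = sum(self.mirna_length_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"mirna_length_dist sums to {total}, expected 1")
        if any(l < 1 for l in self.mirna_length_dist):
            raise ConfigError("miRNA lengths must be positive")
        lo, hi = self.hairpin_length_range
        if lo > hi or lo < 3 * max(self.mirna_length_dist) // 1:
            raise ConfigError("hairpin_length_range infeasible")
        tlo, thi = self.transcript_length_range
        max_len = max(self.mirna_length_dist)
        if tlo > thi or tlo < max_len + 60:
            raise ConfigError("transcripts too short to host a target site with flanks")
        if not 0 < self.gc_target < 1:
            raise ConfigError("gc_target must be in (0, 1)")
        if self.effect_log2fc < 0 or self.dispersion < 0:
            raise ConfigError("effect_log2fc and dispersion must be non-negative")
        if len(self.module_class_mix) != 4 or any(w < 0 for w in self.module_class_mix):
            raise ConfigError("module_class_mix needs 4 non-negative weights")
        if sum(self.module_class_mix) <= 0:
            raise ConfigError("module_class_mix must have positive total weight")
        if not 0 <= self.site_mismatches <= 3:
            raise ConfigError("site_mismatches must be 0..3")


@dataclass(frozen=True)
class TruthModule:
    """One planted miRNA-target regulatory module."""

    mirna_id: str
    transcript_id: str
    site_start: int      # 1-based, inclusive
    site_end: int        # 1-based, inclusive
    cleavage_pos: int    # transcript coordinate opposite miRNA position 10
    klass: str           # one of MODULE_CLASSES
    de_genotype: str     # genotype carrying the planted treatment effect
    timepoints_h: tuple[float, ...]
    mirna_effect: float  # signed log2 fold change of the miRNA (target gets the negation)

    def __post_init__(self) -> None:
        if self.klass not in MODULE_CLASSES:
            raise ConfigError(f"unknown module class {self.klass!r}")
        if self.de_genotype not in GENOTYPES:
            raise ConfigError(f"unknown genotype {self.de_genotype!r}")

    @property
    def silent_genotype(self) -> str | None:
        """The genotype in which the pair is planted as unexpressed, if any."""
        if self.klass == "ST_specific_expression":
            return "SS"
        if self.klass == "SS_specific_expression":
            return "ST"
        return None

    @property
    def pair_key(self) -> tuple[str, str, int]:
        return (self.mirna_id, self.transcript_id, self.cleavage_pos)


@dataclass
class TruthSet:
    """Everything the generator planted, for recovery scoring."""

    modules: list[TruthModule]
    baseline_mirna: dict[str, float]
    baseline_mrna: dict[str, float]
    config: SimConfig

    def validate(self, mirnas: Sequence[SequenceRecord],
                 transcripts: Sequence[SequenceRecord]) -> None:
        mir_ids = {m.id for m in mirnas}
        tx_len = {t.id: len(t) for t in transcripts}
        for mod in self.modules:
            if mod.mirna_id not in mir_ids:
                raise ConfigError(f"truth module references unknown miRNA {mod.mirna_id}")
            if mod.transcript_id not in tx_len:
                raise ConfigError(f"truth module references unknown transcript {mod.transcript_id}")
            if not 1 <= mod.site_start <= mod.site_end <= tx_len[mod.transcript_id]:
                raise ConfigError(f"truth site out of bounds on {mod.transcript_id}")
            if not mod.site_start <= mod.cleavage_pos <= mod.site_end:
                raise ConfigError(f"truth cleavage position outside site on {mod.transcript_id}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "baseline_mirna": self.baseline_mirna,
            "baseline_mrna": self.baseline_mrna,
            "modules": [dataclasses.asdict(m) for m in self.modules],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        cfg_d = payload["config"]
        cfg_d["mirna_length_dist"] = {int(k): v for k, v in cfg_d["mirna_length_dist"].items()}
        for key in ("hairpin_length_range", "transcript_length_range", "module_class_mix"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = SimConfig(**cfg_d)
        modules = [
            TruthModule(**{**m, "timepoints_h": tuple(m["timepoints_h"])})
            for m in payload["modules"]
        ]
        return cls(modules, payload["baseline_mirna"], payload["baseline_mrna"], cfg)


def _substream(cfg: SimConfig, name: str) -> np.random.Generator:
    """Independent, deterministic RNG stream per generator stage."""
    key = int.from_bytes(name.encode(), "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(key,)))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    hits = rng.random(len(out)) < rate
    for i in np.flatnonzero(hits):
        choices = [b for b in "ACGU" if b != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _non_pairing_base(rng: np.random.Generator, mirna_base: str) -> str:
    choices = [b for b in "ACGU" if (mirna_base, b) not in CAN_PAIR]
    return choices[rng.integers(len(choices))]


def _class_counts(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n modules over the 4 classes."""
    total = float(sum(weights))
    quotas = [n * w / total for w in weights]
    counts = [int(q) for q in quotas]
    remainders = sorted(range(4), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def simulate_sequences(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> tuple[list[SequenceRecord], list[SequenceRecord],
                                  list[SequenceRecord], TruthSet]:
    """Generate miRNAs, hairpin precursors, transcripts, and the truth set.

    Precursors are symmetric stem-loops (one arm the noisy reverse complement
    of the other) with the mature miRNA embedded verbatim on one arm. Each
    planted target transcript carries the reverse complement of its miRNA
    (with ``site_mismatches`` seed-distal mismatches) at the recorded site.
    """
    cfg.validate()
    if rng is None:
        rng = _substream(cfg, "sequences")

    lengths = sorted(cfg.mirna_length_dist)
    probs = np.array([cfg.mirna_length_dist[l] for l in lengths])
    probs = probs / probs.sum()

    mirnas: list[SequenceRecord] = []
    precursors: list[SequenceRecord] = []
    for i in range(cfg.n_mirna):
        L = int(rng.choice(lengths, p=probs))
        mat = random_seq(rng, L, cfg.gc_target)
        mid = f"sim-miR{i + 1:03d}"
        mirnas.append(SequenceRecord(mid, mat))

        lo, hi = cfg.hairpin_length_range
        plen = int(rng.integers(lo, hi + 1))
        loop_len = int(rng.integers(6, 11))
        arm = (plen - loop_len) // 2
        loop_len = plen - 2 * arm  # absorb parity so lengths add up exactly
        offset = int(rng.integers(0, arm - L + 1))
        host = random_seq(rng, arm, cfg.gc_target)
        host = host[:offset] + mat + host[offset + L:]
        star = _mutate(rng, revcomp(host), cfg.star_mutation_rate)
        loop = random_seq(rng, loop_len, 0.25)
        arm_choice = "5p" if rng.random() < 0.5 else "3p"
        if arm_choice == "5p":
            pre = host + loop + star
        else:
            pre = revcomp(host) + loop + host  # miRNA lands on the 3' arm
            pre = _mutate(rng, pre[:arm], cfg.star_mutation_rate) + pre[arm:]
        precursors.append(SequenceRecord(f"{mid}-precursor", pre,
                                         description=f"arm={arm_choice}"))

    tlo, thi = cfg.transcript_length_range
    transcripts = []
    for j in range(cfg.n_transcripts):
        tlen = int(rng.integers(tlo, thi + 1))
        transcripts.append(SequenceRecord(f"sim-tx{j + 1:04d}",
                                          random_seq(rng, tlen, cfg.transcript_gc),
                                          written_as_dna=True))

    # --- plant modules -----------------------------------------------------
    mir_idx = rng.choice(cfg.n_mirna, size=cfg.n_true_modules, replace=False)
    tx_idx = rng.choice(cfg.n_transcripts, size=cfg.n_true_modules, replace=False)
    counts = _class_counts(cfg.n_true_modules, cfg.module_class_mix)
    klasses = [MODULE_CLASSES[i] for i, c in enumerate(counts) for _ in range(c)]
    rng.shuffle(klasses)

    modules: list[TruthModule] = []
    for k, (mi, tj) in enumerate(zip(mir_idx, tx_idx)):
        mat = mirnas[mi].seq
        L = len(mat)
        tx = transcripts[tj]
        site = list(revcomp(mat))
        if cfg.site_mismatches:
            # seed-distal mismatches only, and never opposite positions 9-11,
            # so duplex scores stay low and the cleavage site stays canonical
            distal = [p for p in range(14, L + 1) if p not in (9, 10, 11)]
            mm_pos = rng.choice(distal, size=min(cfg.site_mismatches, len(distal)),
                                replace=False)
            for i_mir in sorted(int(p) for p in mm_pos):
                site[L - i_mir] = _non_pairing_base(rng, mat[i_mir - 1])
        site_seq = "".join(site)
        start = int(rng.integers(21, len(tx) - L - 19))  # 1-based start
        new_seq = tx.seq[: start - 1] + site_seq + tx.seq[start - 1 + L:]
        transcripts[tj] = SequenceRecord(tx.id, new_seq, written_as_dna=True)

        klass = klasses[k]
        de_genotype = "ST" if klass in ("DE_in_ST_flat_in_SS", "ST_specific_expression") else "SS"
        n_tp = int(rng.integers(1, 3))
        tps = tuple(sorted(float(t) for t in
                           rng.choice(TIMEPOINTS_H, size=n_tp, replace=False)))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        modules.append(TruthModule(
            mirna_id=mirnas[mi].id,
            transcript_id=tx.id,
            site_start=start,
            site_end=start + L - 1,
            cleavage_pos=start + L - 1 - 9,  # opposite miRNA position 10
            klass=klass,
            de_genotype=de_genotype,
            timepoints_h=tps,
            mirna_effect=sign * cfg.effect_log2fc,
        ))

    # --- baseline abundances ----------------------------------------------
    rel_mir = rng.lognormal(mean=0.0, sigma=1.2, size=cfg.n_mirna)
    base_mir = rel_mir / rel_mir.sum() * cfg.depth_per_library
    rel_tx = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_transcripts)
    base_tx = rel_tx / rel_tx.sum() * cfg.mrna_depth_per_library
    baseline_mirna = {m.id: float(b) for m, b in zip(mirnas, base_mir)}
    baseline_mrna = {t.id: float(b) for t, b in zip(transcripts, base_tx)}
    for mod in modules:
        baseline_mirna[mod.mirna_id] = max(baseline_mirna[mod.mirna_id],
                                           cfg.min_planted_baseline)
        baseline_mrna[mod.transcript_id] = max(baseline_mrna[mod.transcript_id],
                                               cfg.min_planted_baseline)

    truth = TruthSet(modules, baseline_mirna, baseline_mrna, cfg)
    truth.validate(mirnas, transcripts)
    return mirnas, precursors, transcripts, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(cfg: SimConfig, truth: TruthSet,
                    design: Sequence[LibraryDesign] | None = None,
                    rng: np.random.Generator | None = None
                    ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Draw the miRNA tag-count and transcript count matrices.

    Planted effects multiply the baseline mean by ``2**effect`` in the
    (de_genotype, NaCl, affected-timepoint) cells; the target transcript
    receives the opposite-signed effect. Genotype-specific modules get the
    near-zero silent baseline in every library of the other genotype.
    """
    cfg.validate()
    if design is None:
        design = full_factorial_design()
    if rng is None:
        rng = _substream(cfg, "counts")

    mir_ids = sorted(truth.baseline_mirna)
    tx_ids = sorted(truth.baseline_mrna)

    def build_means(ids: list[str], baselines: Mapping[str, float], is_mirna: bool
                    ) -> np.ndarray:
        means = np.tile(np.array([baselines[f] for f in ids])[:, None], (1, len(design)))
        row = {f: i for i, f in enumerate(ids)}
        for mod in truth.modules:
            fid = mod.mirna_id if is_mirna else mod.transcript_id
            if fid not in row:
                continue
            i = row[fid]
            effect = mod.mirna_effect if is_mirna else -mod.mirna_effect
            for j, d in enumerate(design):
                if mod.silent_genotype is not None and d.genotype == mod.silent_genotype:
                    means[i, j] = cfg.silent_baseline
                elif (d.genotype == mod.de_genotype and d.condition == "NaCl"
                      and d.timepoint_h in mod.timepoints_h):
                    means[i, j] = means[i, j] * 2.0 ** effect
        return means

    mir_means = build_means(mir_ids, truth.baseline_mirna, True)
    tx_means = build_means(tx_ids, truth.baseline_mrna, False)

    if cfg.depth_jitter > 0:
        factors = np.exp(rng.normal(0.0, cfg.depth_jitter, size=len(design)))
        mir_means = mir_means * factors[None, :]
        tx_means = tx_means * factors[None, :]

    mir_counts = _nb_draw(rng, mir_means, cfg.dispersion)
    tx_counts = _nb_draw(rng, tx_means, cfg.dispersion)
    lib_ids = [d.library_id for d in design]
    return (
        ExpressionMatrix(pd.DataFrame(mir_counts, index=mir_ids, columns=lib_ids),
                         list(design)),
        ExpressionMatrix(pd.DataFrame(tx_counts, index=tx_ids, columns=lib_ids),
                         list(design)),
    )


def simulate_degradome(cfg: SimConfig, truth: TruthSet,
                       transcripts: Sequence[SequenceRecord],
                       rng: np.random.Generator | None = None
                       ) -> dict[str, dict[str, DegradomeProfile]]:
    """One pooled degradome profile per genotype.

    Planted cleavage sites receive Poisson(peak_rate * degradome_depth)
    reads; every other position receives Poisson(background_cleavage_rate)
    reads. Modules planted as unexpressed in a genotype leave no peak in
    that genotype's profile.
    """
    cfg.validate()
    if rng is None:
        rng = _substream(cfg, "degradome")
    peak_mean = cfg.degradome_peak_rate * cfg.degradome_depth
    out: dict[str, dict[str, DegradomeProfile]] = {}
    for genotype in GENOTYPES:
        profiles: dict[str, DegradomeProfile] = {}
        for tx in transcripts:
            bg = rng.poisson(cfg.background_cleavage_rate, size=len(tx))
            positions = {int(p) + 1: int(c) for p, c in zip(*[np.flatnonzero(bg), bg[bg > 0]])}
            if positions:
                profiles[tx.id] = DegradomeProfile(tx.id, positions, length=len(tx))
        for mod in truth.modules:
            if mod.silent_genotype == genotype:
                continue
            peak = int(rng.poisson(peak_mean))
            if peak == 0:
                continue
            prof = profiles.get(mod.transcript_id)
            if prof is None:
                tx_len = next(len(t) for t in transcripts if t.id == mod.transcript_id)
                prof = DegradomeProfile(mod.transcript_id, {}, length=tx_len)
                profiles[mod.transcript_id] = prof
            prof.positions[mod.cleavage_pos] = prof.positions.get(mod.cleavage_pos, 0) + peak
        out[genotype] = profiles
    return out


def simulate_annotation(cfg: SimConfig, rng: np.random.Generator | None = None
                        ) -> dict[str, list[SequenceRecord]]:
    """Decoy annotation sets (rRNA/tRNA/snoRNA/repeat) for tag classification."""
    if rng is None:
        rng = _substream(cfg, "annotation")
    out = {}
    for cls in ("rRNA", "tRNA", "snoRNA", "repeat"):
        out[cls] = [
            SequenceRecord(f"{cls}-{i + 1}", random_seq(rng, int(rng.integers(80, 201)), 0.5))
            for i in range(3)
        ]
    return out


@dataclass
class SimulatedStudy:
    """The full synthetic experiment plus its ground truth."""

    config: SimConfig
    design: list[LibraryDesign]
    mirnas: list[SequenceRecord]
    precursors: list[SequenceRecord]
    transcripts: list[SequenceRecord]
    mirna_counts: ExpressionMatrix
    transcript_counts: ExpressionMatrix
    degradome: dict[str, dict[str, DegradomeProfile]]
    truth: TruthSet

    @property
    def transcript_lengths(self) -> dict[str, int]:
        return {t.id: len(t) for t in self.transcripts}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_design(self.design, outdir / "design.tsv")
        write_fasta(self.mirnas, outdir / "mirnas.fa")
        write_fasta(self.precursors, outdir / "precursors.fa")
        write_fasta(self.transcripts, outdir / "transcripts.fa")
        write_counts(self.mirna_counts, outdir / "mirna_counts.tsv")
        write_counts(self.transcript_counts, outdir / "transcript_counts.tsv")
        for genotype in GENOTYPES:
            write_degradome(self.degradome[genotype], outdir / f"degradome_{genotype}.tsv")
        self.truth.to_json(outdir / "truth.json")


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Run every generator stage off named substreams of ``cfg.seed``."""
    cfg.validate()
    design = full_factorial_design()
    mirnas, precursors, transcripts, truth = simulate_sequences(cfg)
    mirna_counts, transcript_counts = simulate_counts(cfg, truth, design)
    degradome = simulate_degradome(cfg, truth, transcripts)
    return SimulatedStudy(cfg, design, mirnas, precursors, transcripts,
                          mirna_counts, transcript_counts, degradome, truth)


def sample_reads(mirnas: Sequence[SequenceRecord], n_reads: int,
                 rng: np.random.Generator,
                 out_of_range_fraction: float = 0.1,
                 decoys: Sequence[SequenceRecord] = ()) -> list[str]:
    """A minimal raw-read emitter for exercising the length filter.

    Draws mature-miRNA reads plus a fraction of 17-nt / 26-nt fragments and
    optional decoy (rRNA/tRNA/...) substrings. No base-call error model.
    """
    reads = []
    pool = [m.seq for m in mirnas]
    for _ in range(n_reads):
        u = rng.random()
        if u < out_of_range_fraction / 2:
            reads.append(random_seq(rng, 17, 0.5))
        elif u < out_of_range_fraction:
            reads.append(random_seq(rng, 26, 0.5))
        elif decoys and u < out_of_range_fraction + 0.1:
            src = decoys[rng.integers(len(decoys))].seq
            L = int(rng.integers(18, 26))
            start = int(rng.integers(0, len(src) - L + 1))
            reads.append(src[start:start + L])
        else:
            reads.append(pool[rng.integers(len(pool))])
    return reads


def write_fastq(reads: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            dna = seq.replace("U", "T")
            fh.write(f"@read{i + 1}\n{dna}\n+\n{'I' * len(dna)}\n")
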