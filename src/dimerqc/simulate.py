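"""Seeded synthetic small-RNA library generator with known composition.

Emulates the library construct geometry of the two chemistries:

* Illumina: the instrument reads a fixed number of cycles (75 here) starting
  at the first insert base, so a read is
  ``insert + 3' adapter + post-adapter construct`` truncated to the fixed
  length, padded with G beyond the construct end (two-channel chemistry
  reports no-signal as G).  An adapter dimer therefore shows the full 3'
  adapter at read position 0 and, error-free, sequences identically in
  every dimer read — which is why dimers surface as overrepresented
  sequences.
* Ion Torrent: reads are variable-length, ``insert + 3' adapter``; indels
  are applied by default to mimic the platform's dominant error mode.

Per-read classes are drawn from ``(dimer_fraction, short_fraction,
remainder clean)``; clean inserts are feature sequences sampled by
abundance, short inserts are sub-minimum junk fragments, dimers have a
zero-length insert.  Qualities follow a linear decay with Gaussian jitter,
clipped to [2, 40] — the simplest model that exercises quality trimming,
not a claim about real instrument error profiles.

Everything is driven by one seeded generator: identical config + seed give
bit-identical output.  What the generator does *not* emulate: PCR
duplicates, flow-cell/chip density effects, homopolymer error spectra,
or real miRNA sequence content (features are random DNA unless a feature
set is supplied).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import CountMatrix
from .fastq_io import ReadRecord
from .preprocess import PROFILE_PRESETS, PlatformProfile

__all__ = [
    "SimConfig",
    "SimTruth",
    "CohortSim",
    "simulate_library",
    "simulate_cohort",
    "matching_profile",
]

ILLUMINA_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"
ION_ADAPTER3 = "ATCACCGACTGCCCATAGAGAGGAAAGCGG"
# TruSeq small-RNA construct tail read through after the 3' adapter
ILLUMINA_POST_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Composition and noise model of one simulated library.

    ``insert_length_distribution`` is (mean, sd, min, max) in nt for clean
    inserts; ``short_insert_min`` is the smallest insert a SHORT read may
    carry (kept above the classifier's dimer window so truth labels and the
    operational dimer definition use the same boundary).
    ``quality_model`` is (q_start, q_slope_per_base, q_sd).
    ``dimer_bias_coupling`` tilts per-sample feature abundances along a
    fixed direction proportionally to the sample's dimer fraction — the
    knob that turns contamination into an expression batch effect.
    """

    n_reads: int = 10_000
    dimer_fraction: float = 0.1
    short_fraction: float = 0.2
    insert_length_distribution: tuple[float, float, int, int] = (22.0, 3.0, 15, 30)
    n_features: int = 200
    feature_abundances: float | tuple[float, ...] = 1.0
    platform: str = "illumina"
    fixed_read_length: int = 75
    substitution_rate: float = 0.01
    indel_rate: float = 0.01
    quality_model: tuple[float, float, float] = (36.0, -0.05, 2.0)
    dimer_bias_coupling: float = 0.0
    min_length: int = 15
    short_insert_min: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimer_fraction + self.short_fraction > 1 + 1e-12:
            raise ValueError("dimer_fraction + short_fraction must be <= 1")
        if not (0 <= self.substitution_rate <= 0.2 and 0 <= self.indel_rate <= 0.2):
            raise ValueError("substitution_rate/indel_rate must be in [0, 0.2]")
        mean, sd, lo, hi = self.insert_length_distribution
        if lo < 1 or hi < lo:
            raise ValueError("insert length bounds must satisfy 1 <= min <= max")
        if not (1 <= self.short_insert_min < self.min_length):
            raise ValueError("need 1 <= short_insert_min < min_length")
        if self.platform not in ("illumina", "iontorrent"):
            raise ValueError("platform must be 'illumina' or 'iontorrent'")

    def noise_free(self) -> "SimConfig":
        """Copy of this config with all error/noise sources switched off."""
        return dataclasses.replace(
            self,
            substitution_rate=0.0,
            indel_rate=0.0,
            quality_model=(self.quality_model[0], 0.0, 0.0),
        )


@dataclass
class SimTruth:
    """Ground truth of a simulated library.

    ``reads`` has one row per read (read_id, true_class, true_feature,
    true_insert_length); it is None when the library was generated in
    counts-only mode.  ``fractions`` are the realized per-class fractions;
    ``feature_counts`` sums to the number of CLEAN reads.
    """

    reads: pd.DataFrame | None
    fractions: dict[str, float]
    feature_counts: pd.Series


@dataclass
class CohortSim:
    """A simulated multi-sample cohort plus its ground truth."""

    sample_ids: list[str]
    configs: list[SimConfig]
    truths: list[SimTruth]
    reads: list[list[ReadRecord]] | None
    counts: CountMatrix
    dimer_fractions: list[float]


def matching_profile(config: SimConfig) -> PlatformProfile:
    """The pre-processing profile matching this config's construct geometry.

    Unlike the full Illumina preset this carries no 5'-primer pass: the
    simulator models sequencing starting at the first insert base, so reads
    contain no residual 5' primer to remove.
    """
    preset = PROFILE_PRESETS[
        "illumina-truseq-smallrna"
        if config.platform == "illumina"
        else "iontorrent-smallrna"
    ]
    return dataclasses.replace(
        preset,
        adapter5=None,
        min_length=config.min_length,
        fixed_read_length=(
            config.fixed_read_length if config.platform == "illumina" else None
        ),
    )


def _feature_lengths(rng: np.random.Generator, config: SimConfig, k: int) -> np.ndarray:
    mean, sd, lo, hi = config.insert_length_distribution
    lengths = np.rint(rng.normal(mean, sd, size=k)).astype(int)
    return np.clip(lengths, max(lo, 1), hi)


def make_features(rng: np.random.Generator, config: SimConfig) -> list[str]:
    """Random DNA feature sequences with insert-distribution lengths."""
    lengths = _feature_lengths(rng, config, config.n_features)
    return ["".join(rng.choice(_BASES, size=n)) for n in lengths]


def _abundances(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    spec = config.feature_abundances
    if isinstance(spec, (int, float)):
        return rng.dirichlet(np.full(config.n_features, float(spec)))
    arr = np.asarray(spec, dtype=float)
    if len(arr) != config.n_features or (arr < 0).any() or arr.sum() <= 0:
        raise ValueError("explicit feature_abundances must be a simplex of n_features")
    return arr / arr.sum()


def _mutate(seq: str, rng: np.random.Generator, config: SimConfig) -> str:
    """Apply substitutions, and indels on Ion Torrent, at configured rates."""
    if config.substitution_rate > 0:
        chars = np.array(list(seq))
        hit = rng.random(len(chars)) < config.substitution_rate
        if hit.any():
            shift = rng.integers(1, 4, size=int(hit.sum()))
            codes = np.searchsorted(_BASES, chars[hit])
            chars[hit] = _BASES[(codes + shift) % 4]
        seq = "".join(chars)
    if config.platform == "iontorrent" and config.indel_rate > 0:
        u = rng.random(len(seq))
        out = []
        half = config.indel_rate / 2
        for c, v in zip(seq, u):
            if v < half:
                continue  # deletion
            if v < config.indel_rate:
                out.append(c)
                out.append(str(rng.choice(_BASES)))
            else:
                out.append(c)
        seq = "".join(out)
    return seq


def _qualities(n: int, rng: np.random.Generator, config: SimConfig) -> tuple[int, ...]:
    q0, slope, sd = config.quality_model
    q = q0 + slope * np.arange(n)
    if sd > 0:
        q = q + rng.normal(0.0, sd, size=n)
    return tuple(int(v) for v in np.clip(np.rint(q), 2, 40))


def _construct(insert: str, rng: np.random.Generator, config: SimConfig) -> str:
    if config.platform == "illumina":
        # fixed-cycle instrument reads through the construct; beyond its end
        # two-channel chemistry reports G (no signal), so the tail is
        # deterministic and dimer reads sequence near-identically
        core = insert + ILLUMINA_ADAPTER3 + ILLUMINA_POST_ADAPTER
        L = config.fixed_read_length
        if len(core) < L:
            core = core + "G" * (L - len(core))
        return core[:L]
    return insert + ION_ADAPTER3


def simulate_library(
    config: SimConfig,
    sample_id: str = "sim",
    features: list[str] | None = None,
    abundances: np.ndarray | None = None,
    make_reads: bool = True,
) -> tuple[list[ReadRecord], SimTruth]:
    """Generate one library and its ground truth.

    ``features``/``abundances`` may be supplied to share a feature universe
    across a cohort; otherwise both are drawn from this library's seed.
    With ``make_reads=False`` only the truth (class fractions and feature
    counts) is generated — statistically identical and much faster, for
    cohort-level calibration studies.
    """
    rng = np.random.default_rng(config.seed)
    if features is None:
        features = make_features(rng, config)
    if abundances is None:
        abundances = _abundances(rng, config)
    feature_ids = [f"feat{i:04d}" for i in range(len(features))]

    p = (
        config.dimer_fraction,
        config.short_fraction,
        max(0.0, 1.0 - config.dimer_fraction - config.short_fraction),
    )
    if not make_reads:
        n_dimer, n_short, n_clean = rng.multinomial(config.n_reads, p)
        fcounts = rng.multinomial(n_clean, abundances)
        truth = SimTruth(
            reads=None,
            fractions={
                "dimer": n_dimer / config.n_reads,
                "short": n_short / config.n_reads,
                "clean": n_clean / config.n_reads,
            },
            feature_counts=pd.Series(fcounts, index=feature_ids),
        )
        return [], truth

    classes = rng.choice(3, size=config.n_reads, p=p)
    records: list[ReadRecord] = []
    rows = []
    fcounts = np.zeros(len(features), dtype=np.int64)
    for i, cls in enumerate(classes):
        read_id = f"{sample_id}:r{i:06d}"
        if cls == 0:
            true_class, feat, insert = "DIMER", None, ""
        elif cls == 1:
            true_class, feat = "SHORT", None
            n_ins = int(
                rng.integers(config.short_insert_min, config.min_length)
            )
            insert = "".join(rng.choice(_BASES, size=n_ins))
        else:
            true_class = "CLEAN"
            fi = int(rng.choice(len(features), p=abundances))
            fcounts[fi] += 1
            feat = feature_ids[fi]
            insert = features[fi]
        seq = _mutate(_construct(insert, rng, config), rng, config)
        if not seq:  # indels may, in principle, erase a whole short read
            seq = str(rng.choice(_BASES))
        records.append(ReadRecord(read_id, seq, _qualities(len(seq), rng, config)))
        rows.append((read_id, true_class, feat, len(insert)))

    truth_frame = pd.DataFrame(
        rows, columns=["read_id", "true_class", "true_feature", "true_insert_length"]
    )
    n = config.n_reads
    truth = SimTruth(
        reads=truth_frame,
        fractions={
            "dimer": float((classes == 0).sum()) / n,
            "short": float((classes == 1).sum()) / n,
            "clean": float((classes == 2).sum()) / n,
        },
        feature_counts=pd.Series(fcounts, index=feature_ids),
    )
    return records, truth


def simulate_cohort(
    n_samples: int,
    dimer_fractions: list[float],
    base_config: SimConfig | None = None,
    overrides: list[dict] | None = None,
    make_reads: bool = True,
) -> CohortSim:
    """Simulate a cohort sharing one feature universe; returns truth counts.

    Per-sample seeds are spawned deterministically from the base seed.  The
    count matrix holds the *true* clean-read feature counts per sample.
    When ``base_config.dimer_bias_coupling > 0`` each sample's abundances
    are tilted along a fixed random direction proportionally to its dimer
    fraction (multiplicative logit tilt), creating a dimer-correlated
    expression shift.
    """
    if len(dimer_fractions) != n_samples:
        raise ValueError("need one dimer fraction per sample")
    base = base_config or SimConfig()
    cohort_rng = np.random.default_rng(base.seed)
    features = make_features(cohort_rng, base)
    base_abund = _abundances(cohort_rng, base)
    bias_direction = cohort_rng.normal(size=base.n_features)
    child_seeds = [int(s) % (2**31) for s in
                   np.random.SeedSequence(base.seed).generate_state(n_samples)]

    sample_ids, configs, truths, reads_all = [], [], [], []
    counts = np.zeros((base.n_features, n_samples), dtype=np.int64)
    for s in range(n_samples):
        cfg_kwargs = {"dimer_fraction": float(dimer_fractions[s]),
                      "seed": child_seeds[s]}
        if overrides and overrides[s]:
            cfg_kwargs.update(overrides[s])
        cfg = dataclasses.replace(base, **cfg_kwargs)
        if base.dimer_bias_coupling > 0:
            tilt = np.exp(
                base.dimer_bias_coupling * cfg.dimer_fraction * bias_direction
            )
            abund = base_abund * tilt
            abund = abund / abund.sum()
        else:
            abund = base_abund
        sample_id = f"sample{s + 1:02d}"
        recs, truth = simulate_library(
            cfg, sample_id, features=features, abundances=abund,
            make_reads=make_reads,
        )
        counts[:, s] = truth.feature_counts.to_numpy()
        sample_ids.append(sample_id)
        configs.append(cfg)
        truths.append(truth)
        reads_all.append(recs)

    matrix = CountMatrix(
        features=list(truths[0].feature_counts.index),
        samples=sample_ids,
        counts=counts,
        allow_zero_samples=True,
    )
    return CohortSim(
        sample_ids=sample_ids,
        configs=configs,
        truths=truths,
        reads=reads_all if make_reads else None,
        counts=matrix,
        dimer_fractions=[float(f) for f in dimer_fractions],
    )
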