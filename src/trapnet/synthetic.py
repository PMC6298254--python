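"""Synthetic spectral-count datasets with known ground truth.

Emulates the statistical structure the filter cascade assumes: a pool of
background contaminants detected across bait and control runs alike,
bait-specific interactors that are constitutive, TNF-induced or TNF-lost,
overdispersed (negative-binomial) counts over biological replicates, a few
shared preys binding several baits, deliberate one-hit wonders, and bait
self-identification. Condition-dependent interactors are structural zeros
in their off condition, so dynamics labels have unambiguous ground truth
(a leaky mode adds rare off-condition singletons for stress tests).

The default design mirrors the study layout: 12 baits x 2 conditions x
3 biological replicates plus 15 negative-control experiments. Abundance
parameters are free simulator knobs the real study does not constrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .fdr import PSMRecord
from .counts import (
    DEFAULT_CONDITIONS,
    ROLE_BAIT,
    ROLE_CONTROL,
    CountMatrix,
)
from .filters import classify_strength
from .network import ReferenceInteractionSet

PROFILE_CONSTITUTIVE = "constitutive"
PROFILE_TNF_INDUCED = "TNF_induced"
PROFILE_TNF_LOST = "TNF_lost"
PROFILES = (PROFILE_CONSTITUTIVE, PROFILE_TNF_INDUCED, PROFILE_TNF_LOST)


@dataclass
class SyntheticConfig:
    """Knobs of the simulated Virotrap screen.

    Counts for detected proteins follow a negative binomial with mean
    ``count_mean`` and dispersion (shape) ``count_dispersion``
    (variance = mean + mean^2 / dispersion), zero-truncated so detection
    implies at least one spectral count.
    """

    n_baits: int = 12
    n_controls: int = 15
    n_replicates: int = 3
    conditions: tuple[str, str] = DEFAULT_CONDITIONS
    n_background: int = 150
    background_detect_prob: float = 0.8
    interactors_per_bait: int = 10
    n_shared_preys: int = 6
    profile_mix: dict[str, float] = field(
        default_factory=lambda: {
            PROFILE_CONSTITUTIVE: 0.5,
            PROFILE_TNF_INDUCED: 0.25,
            PROFILE_TNF_LOST: 0.25,
        }
    )
    count_mean: float = 5.0
    count_dispersion: float = 2.0
    one_hit_rate: float = 0.1
    replicate_detect_prob: float = 0.9
    reference_coverage: float = 0.5
    leaky: bool = False
    leak_prob: float = 0.02
    bait_self_counts: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_baits", "n_controls", "n_replicates", "n_background",
                     "interactors_per_bait", "n_shared_preys"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_baits < 1:
            raise ValueError("n_baits must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ValueError("conditions must be two distinct labels")
        for name in ("background_detect_prob", "one_hit_rate",
                     "replicate_detect_prob", "reference_coverage", "leak_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if set(self.profile_mix) - set(PROFILES):
            raise ValueError(f"profile_mix keys must be among {PROFILES}")
        if any(v < 0 for v in self.profile_mix.values()):
            raise ValueError("profile_mix proportions must be >= 0")
        if abs(sum(self.profile_mix.values()) - 1.0) > 1e-9:
            raise ValueError("profile_mix must sum to 1")
        if self.count_mean <= 0:
            raise ValueError("count_mean must be > 0")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be > 0")


@dataclass(frozen=True)
class PlantedInteraction:
    bait: str
    prey: str
    profile: str
    expected_strength: str


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery scoring."""

    planted: list[PlantedInteraction]
    background: set[str]

    def __post_init__(self) -> None:
        preys = {p.prey for p in self.planted}
        clash = preys & self.background
        if clash:
            raise ValueError(f"planted preys collide with background ids: {sorted(clash)}")

    def pairs(self) -> set[tuple[str, str]]:
        return {(p.bait, p.prey) for p in self.planted}

    def pairs_with(self, profile: str | None = None,
                   expected_strength: str | None = None) -> set[tuple[str, str]]:
        return {
            (p.bait, p.prey) for p in self.planted
            if (profile is None or p.profile == profile)
            and (expected_strength is None or p.expected_strength == expected_strength)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.bait, p.prey, p.profile, p.expected_strength) for p in self.planted],
            columns=["bait", "prey", "profile", "expected_strength"],
        ).sort_values(["bait", "prey"], ignore_index=True)


def _nb_positive(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Zero-truncated negative binomial draws (detection implies >= 1 count)."""
    p = dispersion / (dispersion + mean)
    out = rng.negative_binomial(dispersion, p, size=size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.negative_binomial(dispersion, p, size=int(zero.sum()))
        zero = out == 0
    return out


def _active_conditions(profile: str, conditions: tuple[str, str]) -> tuple[str, ...]:
    base, stim = conditions
    if profile == PROFILE_CONSTITUTIVE:
        return (base, stim)
    if profile == PROFILE_TNF_INDUCED:
        return (stim,)
    if profile == PROFILE_TNF_LOST:
        return (base,)
    raise ValueError(f"unknown profile {profile!r}")


def generate_dataset(config: SyntheticConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate one screen: count matrix (with metadata) plus ground truth.

    Identical (config, seed) pairs reproduce identical outputs. Background
    proteins appear stochastically in bait and control columns; planted
    interactors appear only in their own bait's columns, with
    condition-dependent profiles as structural zeros off-condition.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base, stim = config.conditions

    baits = [f"BAIT{i + 1:02d}" for i in range(config.n_baits)]
    meta_rows = []
    for bait in baits:
        for cond in config.conditions:
            for rep in range(1, config.n_replicates + 1):
                meta_rows.append((f"{bait}_{cond}_r{rep}", bait, cond, rep, ROLE_BAIT))
    for i in range(1, config.n_controls + 1):
        meta_rows.append((f"CTRL{i:02d}_r1", f"CTRL{i:02d}", "not_applicable", 1, ROLE_CONTROL))
    meta = pd.DataFrame(
        meta_rows, columns=["experiment_id", "bait", "condition", "replicate", "role"]
    )
    exp_ids = list(meta["experiment_id"])
    col_index = {e: i for i, e in enumerate(exp_ids)}
    n_exp = len(exp_ids)

    rows: dict[str, np.ndarray] = {}

    def row(protein: str) -> np.ndarray:
        if protein not in rows:
            rows[protein] = np.zeros(n_exp, dtype=np.int64)
        return rows[protein]

    # --- background contaminants: detected anywhere with one probability
    for b in range(config.n_background):
        acc = f"BG{b + 1:04d}"
        detected = rng.random(n_exp) < config.background_detect_prob
        if not detected.any():
            continue
        counts = np.zeros(n_exp, dtype=np.int64)
        counts[detected] = _nb_positive(
            rng, config.count_mean, config.count_dispersion, int(detected.sum())
        )
        row(acc)[:] = counts

    planted: list[PlantedInteraction] = []
    profiles = list(config.profile_mix)
    probs = np.array([config.profile_mix[p] for p in profiles], dtype=float)

    def plant(bait: str, prey: str, profile: str, force_one_hit: bool) -> None:
        active = _active_conditions(profile, config.conditions)
        r = row(prey)
        per_condition_sums: dict[str, int] = {}
        for cond in active:
            cols = [col_index[f"{bait}_{cond}_r{rep}"]
                    for rep in range(1, config.n_replicates + 1)]
            if force_one_hit:
                counts = np.zeros(len(cols), dtype=np.int64)
                counts[0] = 1
            else:
                counts = _nb_positive(
                    rng, config.count_mean, config.count_dispersion, len(cols)
                ) * (rng.random(len(cols)) < config.replicate_detect_prob)
                if counts.sum() == 0:
                    counts[0] = 1
            r[cols] += counts
            per_condition_sums[cond] = int(counts.sum())
        if config.leaky:
            for cond in set(config.conditions) - set(active):
                cols = [col_index[f"{bait}_{cond}_r{rep}"]
                        for rep in range(1, config.n_replicates + 1)]
                leak = rng.random(len(cols)) < config.leak_prob
                r[cols] += leak.astype(np.int64)
        strength = classify_strength(max(per_condition_sums.values()))
        planted.append(PlantedInteraction(bait, prey, profile, strength))

    # --- bait-specific interactors
    idx = 0
    for bait in baits:
        for _ in range(config.interactors_per_bait):
            idx += 1
            profile = profiles[rng.choice(len(profiles), p=probs)]
            plant(bait, f"INT{idx:04d}", profile, rng.random() < config.one_hit_rate)

    # --- shared preys binding >= 3 baits (interwoven complex members)
    for s in range(config.n_shared_preys):
        acc = f"SHP{s + 1:02d}"
        k = min(config.n_baits, int(rng.integers(3, 6)))
        chosen = rng.choice(config.n_baits, size=k, replace=False)
        for bi in sorted(chosen):
            plant(baits[bi], acc, PROFILE_CONSTITUTIVE, False)

    # --- bait self-identification (drives self-loop handling downstream)
    if config.bait_self_counts:
        for bait in baits:
            r = row(bait)
            for cond in config.conditions:
                cols = [col_index[f"{bait}_{cond}_r{rep}"]
                        for rep in range(1, config.n_replicates + 1)]
                r[cols] += _nb_positive(
                    rng, max(config.count_mean * 3, 3.0), config.count_dispersion, len(cols)
                )

    counts = pd.DataFrame(
        np.vstack([rows[p] for p in sorted(rows)]) if rows else
        np.zeros((0, n_exp), dtype=np.int64),
        index=sorted(rows),
        columns=exp_ids,
    )
    counts.index.name = "protein"
    truth = GroundTruth(planted=planted, background={f"BG{b + 1:04d}" for b in range(config.n_background)})
    return CountMatrix(counts, meta), truth


def generate_reference_set(
    truth: GroundTruth,
    coverage: float,
    extra_pairs: int = 0,
    seed: int = 0,
) -> ReferenceInteractionSet:
    """Partial-knowledge reference set over the planted interactions.

    Samples ``round(coverage * n_planted)`` planted pairs without
    replacement (as unordered pairs) and adds ``extra_pairs`` decoy pairs
    that were never planted, mimicking a curated database that covers only
    part of the true interactome and contains interactions this screen
    cannot see.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    if extra_pairs < 0:
        raise ValueError("extra_pairs must be >= 0")
    rng = np.random.default_rng(seed)
    planted_pairs = sorted({tuple(sorted(pair)) for pair in truth.pairs()})
    n_take = round(coverage * len(planted_pairs))
    take_idx = rng.choice(len(planted_pairs), size=n_take, replace=False) if n_take else []
    pairs = [planted_pairs[i] for i in sorted(take_idx)]
    forbidden = set(planted_pairs)
    for i in range(extra_pairs):
        pair = tuple(sorted((f"DEC{2 * i + 1:04d}", f"DEC{2 * i + 2:04d}")))
        assert pair not in forbidden
        pairs.append(pair)
    return ReferenceInteractionSet(pairs, version_label=f"synthetic-coverage-{coverage}")


def generate_psms(
    n_spectra: int,
    decoy_hit_prob: float = 0.05,
    max_matches_per_spectrum: int = 3,
    seed: int = 0,
) -> list[PSMRecord]:
    """Synthetic PSM lists for exercising the target/decoy FDR machinery.

    Each spectrum receives 1..max matches with Gaussian scores; each match
    is a decoy hit with probability ``decoy_hit_prob``. Decoy scores are
    drawn from a slightly lower-scoring distribution, as reversed-database
    matches are in practice.
    """
    rng = np.random.default_rng(seed)
    psms: list[PSMRecord] = []
    for s in range(1, n_spectra + 1):
        sid = f"spec{s:06d}"
        for m in range(int(rng.integers(1, max_matches_per_spectrum + 1))):
            is_decoy = bool(rng.random() < decoy_hit_prob)
            loc = 30.0 if is_decoy else 40.0
            score = float(np.round(rng.normal(loc, 8.0), 3))
            protein = f"REV_P{s:05d}" if is_decoy else f"P{s:05d}"
            peptide = "PEPTIDE" + str(m)
            psms.append(PSMRecord(sid, protein, peptide, score, is_decoy))
    return psms
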