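import numpy as np
import pandas as pd
import pytest

from trapnet import CountMatrix, SyntheticConfig, generate_dataset


def make_meta(n_baits=2, n_controls=2, n_replicates=2, conditions=("untreated", "TNF")):
    rows = []
    for b in range(1, n_baits + 1):
        bait = f"B{b}"
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                rows.append((f"{bait}_{cond}_r{rep}", bait, cond, rep, "bait_experiment"))
    for c in range(1, n_controls + 1):
        rows.append((f"C{c}", f"CB{c}", "not_applicable", 1, "control_experiment"))
    return pd.DataFrame(
        rows, columns=["experiment_id", "bait", "condition", "replicate", "role"]
    )


def make_matrix(row_counts: dict, meta: pd.DataFrame) -> CountMatrix:
    """Build a CountMatrix from {protein: {experiment_id: count}}."""
    exp_ids = list(meta["experiment_id"])
    data = {
        p: [int(cols.get(e, 0)) for e in exp_ids] for p, cols in row_counts.items()
    }
    counts = pd.DataFrame.from_dict(data, orient="index", columns=exp_ids).astype(np.int64)
    return CountMatrix(counts, meta)


def random_small_matrix(rng, max_proteins=6):
    """A random valid matrix with <= 6 proteins x <= 8 experiments."""
    n_baits = int(rng.integers(1, 3))
    n_controls = int(rng.integers(1, 3))
    n_reps = int(rng.integers(1, 3))
    meta = make_meta(n_baits=n_baits, n_controls=n_controls, n_replicates=n_reps)
    if len(meta) > 8:  # 2 baits x 2 conds x 2 reps + controls can exceed 8
        meta = pd.concat(
            [meta[meta["role"] == "bait_experiment"].iloc[:6],
             meta[meta["role"] == "control_experiment"].iloc[:2]],
            ignore_index=True,
        )
    n_prot = int(rng.integers(1, max_proteins + 1))
    rows = {}
    for i in range(n_prot):
        row = rng.choice([0, 0, 0, 1, 1, 2, 3], size=len(meta))
        if row.sum() == 0:
            row[int(rng.integers(0, len(meta)))] = 1
        rows[f"P{i + 1}"] = dict(zip(meta["experiment_id"], (int(x) for x in row)))
    return make_matrix(rows, meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic screen shared across read-only tests."""
    config = SyntheticConfig(seed=11)
    matrix, truth = generate_dataset(config)
    return config, matrix, truth


@pytest.fixture()
def small_meta():
    return make_meta()


@pytest.fixture()
def small_matrix(small_meta):
    # BG1 is background (control hit), P1-P3 bait-specific with varied support
    rows = {
        "BG1": {"C1": 1, "B1_untreated_r1": 50, "B2_TNF_r1": 4},
        "P1": {"B1_untreated_r1": 1, "B1_untreated_r2": 1},          # weak
        "P2": {"B1_TNF_r1": 2, "B1_TNF_r2": 3, "B1_untreated_r1": 1},  # strong + one-hit
        "P3": {"B2_untreated_r1": 1},                                  # one-hit wonder
    }
    return make_matrix(rows, small_meta)
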