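import pytest

from mfpt import (
    MiningParams,
    RuleMiningParams,
    Transaction,
    TransactionDB,
    train_model,
)
from mfpt.synthetic import benchmark_spec, generate, truth_table

# the five-transaction worked example: items bought per transaction
WORKED_EXAMPLE_ROWS = {
    1: "FACDGIM",
    2: "ABCFLMO",
    3: "BFHJO",
    4: "BCKS",
    5: "AFCELMN",
}
# published frequency-descending item order at min support 3
WORKED_EXAMPLE_ORDER = "FCABM"

BENCHMARK_SEED = 1


@pytest.fixture(scope="session")
def worked_example_db() -> TransactionDB:
    return TransactionDB(
        [Transaction(str(tid), set(row)) for tid, row in WORKED_EXAMPLE_ROWS.items()]
    )


@pytest.fixture(scope="session")
def worked_example_params() -> MiningParams:
    return MiningParams(min_support=3, item_order_override=WORKED_EXAMPLE_ORDER)


@pytest.fixture(scope="session")
def benchmark():
    """The standard planted-rule benchmark: (spec, db, truth rows)."""
    spec = benchmark_spec(seed=BENCHMARK_SEED)
    db = generate(spec)
    return spec, db, truth_table(spec, db)


@pytest.fixture(scope="session")
def benchmark_model(benchmark):
    """Rule sets mined from the benchmark at the standard thresholds.

    Session-scoped: training visits every compartment's full greedy loop.
    """
    _, db, _ = benchmark
    params = RuleMiningParams(min_support=2, min_hit_rate=0.5)
    return train_model(db, ["C", "N", "M", "T", "E"], params)


@pytest.fixture
def small_labeled_db() -> TransactionDB:
    """Ten hand-built transactions: items {1,2} co-occur in four rows, three
    of which are labeled N (hit-rate 3/4 for rule {1,2} -> N)."""
    rows = [
        ({1, 2, 5}, "N"),
        ({1, 2, 6}, "N"),
        ({1, 2, 7}, "N"),
        ({1, 2, 8}, "C"),
        ({1, 5, 9}, "C"),
        ({2, 6, 9}, "C"),
        ({3, 4, 5}, "M"),
        ({3, 4, 6}, "M"),
        ({5, 7, 9}, "N"),
        ({6, 8, 9}, "C"),
    ]
    return TransactionDB(
        [Transaction(f"P{i}", items, lab) for i, (items, lab) in enumerate(rows, 1)]
    )
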