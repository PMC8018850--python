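import pytest

from acumine import MiningParams, TransactionDB, dgp_fixture

#: The five-transaction textbook database used across mining tests.
TOY_TRANSACTIONS = [
    {"A", "B", "C"},
    {"A", "B"},
    {"A", "C"},
    {"B", "C"},
    {"A", "B", "C"},
]


@pytest.fixture(scope="session")
def dgp_db() -> TransactionDB:
    """Bundled 17-trial database, supports over the transaction count."""
    return dgp_fixture()


@pytest.fixture(scope="session")
def dgp_db_formulas() -> TransactionDB:
    """Bundled database under the 14-formula reporting convention."""
    return dgp_fixture("formulas")


@pytest.fixture
def toy_db() -> TransactionDB:
    return TransactionDB.from_itemsets(TOY_TRANSACTIONS)


@pytest.fixture
def toy_params() -> MiningParams:
    return MiningParams(min_support=0.6)
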