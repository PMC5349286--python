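import numpy as np
import pytest

from rumenh2 import FluxTable, fixture, mean_record, reference_gas_mmol
from rumenh2.fixtures import TREATMENTS

LEDGER_FLUX_PRODUCTS = ("formate", "acetate", "propionate", "butyrate",
                        "valerate", "caproate", "heptanoate", "ch4", "h2")


@pytest.fixture(scope="session")
def mean_records():
    """One treatment-mean record per treatment of the reference experiment."""
    return {trt: mean_record(trt) for trt in TREATMENTS}


@pytest.fixture(scope="session")
def reference_gas():
    """Per-gas mmol/d per treatment, on the [2H]-table basis."""
    return {trt: reference_gas_mmol(trt) for trt in TREATMENTS}


@pytest.fixture(scope="session")
def t7():
    return fixture("T7")


def random_flux_tables(n: int, seed: int = 0, scale: float = 50.0):
    """Seeded random flux tables over all ledger products (plus branched-chain)."""
    rng = np.random.default_rng(seed)
    tables = []
    for i in range(n):
        fluxes = {p: float(rng.uniform(0.0, scale))
                  for p in LEDGER_FLUX_PRODUCTS}
        fluxes["isobutyrate"] = float(rng.uniform(0.0, scale))
        fluxes["isovalerate"] = float(rng.uniform(0.0, scale))
        tables.append(FluxTable(unit_id=f"rand-{i}", fluxes=fluxes))
    return tables
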