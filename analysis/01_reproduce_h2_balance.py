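#!/usr/bin/env python
"""Rebuild the reference [2H]-balance table from printed treatment means.

Takes the shipped treatment-mean fermentation inputs (total VFA, molar
shares, saliva outflow, per-gas moles on the [2H]-table basis), runs them
through the flux/ledger pipeline under both caproate scenarios, and writes
the recomputed table next to the printed one with their differences.

Finding: every pure mean-arithmetic cell (acetate, propionate, valerate,
heptanoate, the control totals and balances) lands on the printed value;
cells the source computed from per-vessel data drift by up to ~0.4 mmol/d,
and the printed NOP/AQ balance rows are not even consistent with the
printed totals they should equal (least-square means under unbalanced
missingness do not respect linear identities).
"""

import argparse
from pathlib import Path

import pandas as pd

from rumenh2 import display_round, h2_balance_report, mean_record, write_results
from rumenh2.fixtures import TREATMENTS, fixture, reference_gas_mmol


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    records = [mean_record(t) for t in TREATMENTS]
    gas = {t: reference_gas_mmol(t) for t in TREATMENTS}
    computed = display_round(h2_balance_report(records, gas_mmol=gas))
    printed = fixture("T7").to_frame()

    comparison = pd.concat(
        {"computed": computed[list(TREATMENTS)],
         "printed": printed[list(TREATMENTS)]},
        axis=1)
    diff = (computed[list(TREATMENTS)] - printed[list(TREATMENTS)]).round(2)

    write_results({
        "h2_balance_recomputed": computed.reset_index(),
        "h2_balance_printed": printed.reset_index(),
        "h2_balance_diff": diff.reset_index(),
    }, args.out)

    print("Recomputed [2H] balance (rows x treatments):")
    print(computed[list(TREATMENTS)].to_string())
    print("\nDifference to printed table (computed - printed):")
    print(diff.to_string())
    exact = ["acetate_production", "propionate_consumption",
             "valerate_consumption", "heptanoate_consumption"]
    print("\nExactly reproduced for CON:",
          all(diff.loc[r, "CON"] == 0 for r in exact))
    print(f"Tables written to {args.out}/")


if __name__ == "__main__":
    main()
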