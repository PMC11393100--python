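#!/usr/bin/env python
"""Quality control of raw sonde records.

Generates a deliberately dirty raw telemetry table (DO spikes above the
25 mg/L ceiling, non-positive probe readings, duplicated timestamps, a
redundant salinity column), runs the QC rule set, pairs the daily rainfall
series onto the 15-minute rows, and writes the reconciled QC report.
"""

import argparse
import json
from pathlib import Path

from doflux import SyntheticConfig, apply_qc_filters, generate_raw_site, pair_rainfall


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = SyntheticConfig(n_days=30, seed=args.seed)
    raw, rain = generate_raw_site(cfg, site_id="SYN1", dist_to_sea_km=12.0)
    series, report = apply_qc_filters(raw, site_id="SYN1", dist_to_sea_km=12.0)
    series = pair_rainfall(series, rain)

    report.to_json(args.out_dir / "qc_report.json")
    print(f"rows in: {report.rows_in}, rows out: {report.rows_out}")
    for rule, n in sorted(report.rows_removed_by_rule.items()):
        print(f"  removed by {rule}: {n}")
    print(f"dropped columns: {report.dropped_columns}")
    print(f"report reconciles: {report.reconciles()}")
    n_missing_rain = int(series.data["rainfall_mm"].isna().sum())
    print(f"rainfall paired by calendar date; rows without a rain value: {n_missing_rain}")
    print(f"wrote {args.out_dir / 'qc_report.json'}")


if __name__ == "__main__":
    main()
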