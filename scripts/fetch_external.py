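#!/usr/bin/env python
"""OPTIONAL: download external datasets for large-scale reproductions.

The core test suite is download-free.  This helper fetches the UCI adult
census dataset (32,561 rows) so the engine can be exercised at realistic
scale; it is never run by the tests or the acceptance script and requires
network access.

Usage:  python scripts/fetch_external.py --dest scratch/external
"""

from __future__ import annotations

import argparse
import urllib.request
from pathlib import Path

ADULT_URL = (
    "https://archive.ics.uci.edu/ml/machine-learning-databases/adult/adult.data"
)
ADULT_COLUMNS = (
    "age,workclass,fnlwgt,education,education-num,marital-status,occupation,"
    "relationship,race,sex,capital-gain,capital-loss,hours-per-week,"
    "native-country,salary-class"
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path, default=Path("scratch/external"))
    args = parser.parse_args()
    args.dest.mkdir(parents=True, exist_ok=True)
    out = args.dest / "adult.csv"
    print(f"downloading {ADULT_URL} ...")
    with urllib.request.urlopen(ADULT_URL) as resp:
        body = resp.read().decode("utf-8")
    rows = [line.replace(", ", ",") for line in body.splitlines() if line.strip()]
    out.write_text(ADULT_COLUMNS + "\n" + "\n".join(rows) + "\n", encoding="utf-8")
    print(f"wrote {out} ({len(rows)} rows)")


if __name__ == "__main__":
    main()
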