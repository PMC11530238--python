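#!/usr/bin/env python
"""Download the deposited mmCIF files used by configs/trpm_conservation.yaml.

Requires network access; the analysis pipelines themselves never download
anything implicitly.
"""
import sys
import urllib.request
from pathlib import Path

ACCESSIONS = ["7wre", "6nr3", "7mbq", "6bqv", "6co7", "8ddr", "6v9w", "6ot5"]
DEST = Path(__file__).resolve().parents[1] / "data" / "structures"


def main() -> int:
    DEST.mkdir(parents=True, exist_ok=True)
    failures = []
    for acc in ACCESSIONS:
        out = DEST / f"{acc}.cif"
        if out.exists():
            print(f"{acc}: already present")
            continue
        url = f"https://files.rcsb.org/download/{acc.upper()}.cif"
        try:
            print(f"{acc}: fetching {url}")
            urllib.request.urlretrieve(url, out)
        except OSError as exc:
            failures.append(acc)
            print(f"{acc}: FAILED ({exc})", file=sys.stderr)
    if failures:
        print(f"failed: {', '.join(failures)}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":
    sys.exit(main())
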