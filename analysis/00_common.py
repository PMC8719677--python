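"""Shared plumbing for the numbered analysis drivers.

Each driver reads/writes under a study directory (default ``results/study``)
and accepts ``--seed`` and ``--full``. The default library is scaled down
(600 promoters, 2,000 events per promoter x condition) so the whole chain
runs in well under a minute on a laptop; ``--full`` switches to the
library-scale defaults (1,810 promoters, 5,000 events).
"""

from __future__ import annotations

import argparse
from pathlib import Path

SMALL = dict(P=600, n_events=2000)


def study_parser(description: str) -> argparse.ArgumentParser:
    p = argparse.ArgumentParser(description=description)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--study-dir", type=Path, default=Path("results/study"))
    p.add_argument("--full", action="store_true",
                   help="library-scale defaults instead of the quick subset")
    return p


def simulate_kwargs(args) -> dict:
    return {} if args.full else dict(SMALL)
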