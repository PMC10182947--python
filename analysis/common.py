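"""Shared configuration for the numbered analysis drivers.

Every driver reruns the seeded study through the mechtox pipeline (runs are
bit-reproducible, so each stage sees exactly the same data) and writes its
summary tables under results/.
"""

from pathlib import Path

from mechtox import run_demo_study

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

_cache = {}


def study():
    if "res" not in _cache:
        _cache["res"] = run_demo_study(seed=SEED, keep_artifacts=True)
    return _cache["res"]


def outdir() -> Path:
    RESULTS.mkdir(exist_ok=True)
    return RESULTS
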