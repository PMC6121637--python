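"""Bundled example data.

A published per-sample cytosine-context tally from a whole-genome
bisulfite study of bicolored ornamental-tree petals: two conditions
(WT = white petal tissue, RT = red petal tissue), three biological
replicates each, with the number of reference cytosines and the number
called methylated per sequence context.  Useful as a worked example
for :func:`methlink.methylation.summarize_context_counts` — the
summary arithmetic (ratios, condition averages, context shares)
reproduces the study's reported percentages from these counts alone.
"""

from __future__ import annotations

import pandas as pd

_SITES = {"CG": 8_335_974, "CHG": 11_664_623, "CHH": 62_367_490}

_METHYLATED = {
    "WT1": {"CG": 3_193_016, "CHG": 2_275_905, "CHH": 3_833_891},
    "WT2": {"CG": 3_153_580, "CHG": 2_396_865, "CHH": 6_156_465},
    "WT3": {"CG": 3_015_038, "CHG": 2_258_108, "CHH": 5_709_047},
    "RT1": {"CG": 3_086_648, "CHG": 2_350_640, "CHH": 6_171_940},
    "RT2": {"CG": 3_170_368, "CHG": 2_434_099, "CHH": 6_386_536},
    "RT3": {"CG": 3_411_185, "CHG": 2_580_335, "CHH": 6_231_272},
}


def petal_context_counts() -> pd.DataFrame:
    """Per-sample methylated-site counts by context (tidy).

    Columns: sample, context, n_sites, n_methylated.  The site universe
    (reference cytosines per context) is shared across samples.
    """
    rows = [
        {
            "sample": sample,
            "context": context,
            "n_sites": _SITES[context],
            "n_methylated": n,
        }
        for sample, per_ctx in _METHYLATED.items()
        for context, n in per_ctx.items()
    ]
    return pd.DataFrame(rows)


def petal_conditions() -> dict[str, str]:
    """Sample -> condition map for the bundled petal counts."""
    return {s: s[:2] for s in _METHYLATED}
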