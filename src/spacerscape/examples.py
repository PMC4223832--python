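"""Documented worked examples shipped with the package.

``self_targeting_examples`` returns published self-targeting spacers from
*Salinispora arenicola* strains together with the chromosomal regions they
match (the region lines carry a few adjacent nucleotides on either side of
the protospacer).  They exercise both match categories: two spacers have a
full-coverage, 100%-identity chromosomal hit, while the cytochrome-P450
spacer of strain CNX-481 agrees with its chromosomal region only over its
first 32 nt — a partial (>=18 nt exact) hit, not a perfect one.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd


def self_targeting_examples() -> pd.DataFrame:
    """Table with columns strain, gene, spacer, chromosomal_region."""
    ref = importlib.resources.files("spacerscape.data").joinpath(
        "self_targeting_examples.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")
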