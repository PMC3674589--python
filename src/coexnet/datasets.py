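"""Small reference tables bundled with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_concordance_reference() -> pd.DataFrame:
    """Published table of 25 genes with concordant disease-progression patterns.

    Columns: Progression (+/-), GeneSymbol, corHuman (correlation with the
    0/1/2 human disease coding), p.Human, corMouse (correlation with mouse
    week of age), p.Mouse, MM.magenta (membership in the immune-infiltration
    module).  Used to validate the concordant-gene selection rule against a
    published selection.
    """
    with resources.files("coexnet.data").joinpath("concordance_reference.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
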