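"""Packaged reference tables.

Currently one table: per-protein Q3 accuracies of the PSRSM and DeepCNF
web servers on the T100 benchmark (100 PDB chains released in early
2018, lengths 18-1460).  Four chains fall outside the DeepCNF server's
26-4000 residue limits and carry no DeepCNF value.  The table is used
as a worked example for the dataset-level averaging arithmetic.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_t100_table() -> pd.DataFrame:
    """The T100 per-protein server accuracies.

    Returns a DataFrame with columns ``id``, ``length``, ``psrsm_q3``
    and ``deepcnf_q3`` (NaN where the DeepCNF server could not process
    the chain).
    """
    ref = resources.files("psrsm.data") / "t100_server_q3.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])
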