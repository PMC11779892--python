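"""Shared fixtures: small repertoires, clone sets, and AnnData objects."""

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData

from clonotrack.repertoire import Repertoire, collapse_to_clones


def make_repertoire(rows, donor="d1", compartment="liver"):
    """Repertoire from (junction, v, j, count, productive) tuples."""
    df = pd.DataFrame(
        rows, columns=["junction", "v_call", "j_call", "duplicate_count", "productive"]
    )
    return Repertoire(donor, compartment, df)


def make_clone_set(counts, donor="d1", compartment="liver", prefix="SEQ"):
    """CloneSet with synthetic junctions SEQ000.. and the given read counts."""
    rows = [
        (f"{prefix}{i:03d}", "TRBV9-1*01", "TRBJ1-1*01", c, True)
        for i, c in enumerate(counts)
    ]
    return collapse_to_clones(make_repertoire(rows, donor, compartment))


@pytest.fixture
def small_repertoire():
    return make_repertoire(
        [
            ("TGTGCCAGCAGTTTTGGA", "TRBV9-1*01", "TRBJ1-1*01", 5, True),
            ("TGTGCCAGCAAATTTGGA", "TRBV2-1*01", "TRBJ1-2*01", 2, True),
            ("TGTGCCAGCACCTTTGGA", "TRBV4-1*01", "TRBJ2-1*01", 1, True),
        ]
    )


def make_counts_adata(
    X, cluster=None, reactivity=None, gene_prefix="GENE", rng_names=True
):
    """AnnData of raw counts with optional obs annotations."""
    X = np.asarray(X)
    n_obs, n_var = X.shape
    obs = pd.DataFrame(index=pd.Index([f"cell{i:04d}" for i in range(n_obs)]))
    if cluster is not None:
        obs["cluster"] = list(cluster)
    if reactivity is not None:
        obs["reactivity"] = list(reactivity)
    var = pd.DataFrame(index=pd.Index([f"{gene_prefix}{j:04d}" for j in range(n_var)]))
    return AnnData(X=X.astype(float), obs=obs, var=var)
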