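import numpy as np
import pandas as pd
import pytest

from surfbat.panel_io import HaplotypePanel, TargetHaplotypes


def make_panel(haps, positions=None, chrom="1", cm=None, sample_ids=None, group_labels=None):
    """Build a small panel from a (n_sites, n_haps) 0/1 array."""
    haps = np.asarray(haps, dtype=np.uint8)
    n_sites, n_haps = haps.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 1000
    if cm is None:
        cm = np.asarray(positions, dtype=float) / 1e6
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "id": [f"snp{j}" for j in range(n_sites)],
            "ref": "A",
            "alt": "G",
            "cm": np.asarray(cm, dtype=float),
        }
    )
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_haps // 2)]
    return HaplotypePanel(
        sites=sites, haplotypes=haps, sample_ids=sample_ids, group_labels=group_labels
    )


def make_targets(panel, haps, site_index=None, sample_ids=None):
    """TargetHaplotypes over a subset of panel sites from a (n_typed, M) array."""
    haps = np.asarray(haps, dtype=np.uint8)
    if site_index is None:
        site_index = np.arange(panel.n_sites)
    sites = panel.sites.iloc[np.asarray(site_index)].reset_index(drop=True)
    if sample_ids is None:
        sample_ids = [f"C{i}" for i in range(haps.shape[1] // 2)]
    return TargetHaplotypes(typed_sites=sites, haplotypes=haps, sample_ids=sample_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
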