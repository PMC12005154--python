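"""Transmitted (rho) and un-transmitted/pseudo-control (pi) dosages.

For every case haplotype, the copying posterior over reference haplotypes is
turned into an expected ALT dose at every panel site: ``rho`` weights the
copied haplotypes' own alleles, ``pi`` weights their within-individual
partner haplotypes' alleles.  Sites absent from the array are filled by
linear interpolation on the genetic map between the two flanking typed
sites' posteriors — applied to the (rho, pi) functionals directly, which is
identical to interpolating the posterior rows since both are linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ls_hmm import HmmParams, forward_backward_batch
from .panel_io import HaplotypePanel, TargetHaplotypes

logger = logging.getLogger("surfbat")


def partner_index(k):
    """0-based index of the partner haplotype within the same individual.

    Columns 2i and 2i+1 belong to individual i, so the partner of an even
    index is the next one and vice versa; the map is an involution.
    """
    k = np.asarray(k)
    if np.any(k < 0):
        raise ValueError("haplotype index must be non-negative")
    out = np.bitwise_xor(k, 1)
    return int(out) if out.ndim == 0 else out


def partner_permutation(n_haplotypes: int) -> np.ndarray:
    """Permutation sending every haplotype column to its partner's."""
    if n_haplotypes % 2:
        raise ValueError("haplotype count must be even (2 per individual)")
    return partner_index(np.arange(n_haplotypes))


def site_dosage(posterior_row: np.ndarray, panel_alleles_at_site: np.ndarray):
    """(rho, pi) at one site from one posterior row.

    rho = sum_k p_k [H_k = 1];  pi = sum_k p_k [H_partner(k) = 1].
    """
    p = np.asarray(posterior_row, dtype=float)
    a = np.asarray(panel_alleles_at_site, dtype=float)
    if p.shape != a.shape:
        raise ValueError("posterior row and allele vector lengths differ")
    rho = float(p @ a)
    pi = float(p @ a[partner_permutation(a.shape[0])])
    return rho, pi


def interpolate_untyped(left, right, w: float):
    """Linear interpolation between flanking typed-site dosage pairs."""
    if not (0.0 <= w <= 1.0):
        raise ValueError("interpolation weight must lie in [0, 1]")
    lr, lp = left
    rr, rp = right
    return ((1.0 - w) * lr + w * rr, (1.0 - w) * lp + w * rp)


def info_score(rhos: np.ndarray) -> float:
    """Imputation-quality score on haploid doses.

    ``1 - sum_h rho_h (1 - rho_h) / (H * theta (1 - theta))`` with theta the
    mean dose — the ratio-of-variances measure used by imputation engines,
    stated here on haplotype doses.  Defined as 1 when theta is 0 or 1 (no
    dosage uncertainty is possible) and equals 1 whenever every dose is hard.
    """
    r = np.asarray(rhos, dtype=float)
    if r.size < 2:
        raise ValueError("info_score needs at least 2 haplotype doses")
    theta = float(r.mean())
    if theta <= 0.0 or theta >= 1.0:
        return 1.0
    return 1.0 - float((r * (1.0 - r)).sum()) / (r.size * theta * (1.0 - theta))


def case_maf(rhos: np.ndarray) -> float:
    """Minor-allele frequency of the mean imputed case dose."""
    r = np.asarray(rhos, dtype=float)
    if r.size < 1:
        raise ValueError("case_maf needs at least 1 dose")
    theta = float(r.mean())
    return min(theta, 1.0 - theta)


@dataclass
class DosageTable:
    """Per case-haplotype, per panel-site transmitted/un-transmitted doses.

    ``rho`` and ``pi`` have shape (n_case_haplotypes, n_panel_sites);
    ``typed`` flags panel sites present on the array.  ``group_mass`` holds
    the mean posterior copying mass per reference group (over haplotypes and
    typed sites) when the panel carries group labels.
    """

    sites: pd.DataFrame
    rho: np.ndarray
    pi: np.ndarray
    typed: np.ndarray
    hap_ids: list[str]
    group_mass: Optional[pd.Series] = None
    cross_group_mass: Optional[float] = None

    def info_scores(self) -> np.ndarray:
        r = self.rho
        theta = r.mean(axis=0)
        denom = r.shape[0] * theta * (1.0 - theta)
        uncert = (r * (1.0 - r)).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            info = 1.0 - uncert / denom
        return np.where((theta <= 0.0) | (theta >= 1.0), 1.0, info)

    def case_mafs(self) -> np.ndarray:
        theta = self.rho.mean(axis=0)
        return np.minimum(theta, 1.0 - theta)

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: one row per (site, haplotype)."""
        n_hap, n_site = self.rho.shape
        return pd.DataFrame(
            {
                "chrom": np.repeat(self.sites["chrom"].to_numpy(), n_hap),
                "pos": np.repeat(self.sites["pos"].to_numpy(), n_hap),
                "hap_id": np.tile(np.asarray(self.hap_ids, dtype=object), n_site),
                "rho": self.rho.T.ravel(),
                "pi": self.pi.T.ravel(),
                "typed": np.repeat(self.typed, n_hap),
            }
        )


def _match_typed_sites(panel: HaplotypePanel, targets: TargetHaplotypes) -> np.ndarray:
    idx = panel.site_keys().get_indexer(targets.site_keys())
    if np.any(idx < 0):
        missing = targets.typed_sites.iloc[int(np.flatnonzero(idx < 0)[0])]
        raise ValueError(
            f"typed site {missing.chrom}:{missing.pos} {missing.ref}>{missing.alt} "
            "absent from the reference panel"
        )
    if np.any(np.diff(idx) <= 0):
        raise ValueError("typed sites must appear in panel order")
    return idx


def build_dosage_table(
    panel: HaplotypePanel,
    targets: TargetHaplotypes,
    params: HmmParams | None = None,
    chunk_elems: float = 2e7,
) -> DosageTable:
    """Run the copying HMM for every case haplotype and fill all panel sites.

    At typed sites the posterior row is applied to the site's panel alleles;
    between typed sites the (rho, pi) pair is linearly interpolated on the
    genetic map between the two flanking typed-site posteriors applied to the
    untyped site's alleles.  Outside the typed range the nearest typed-site
    posterior is used.  Ties in cM collapse to a 0.5/0.5 average.

    The validity of the pseudo-control rests on the two haplotypes of each
    reference individual sharing similar ancestry; this is not enforced, but
    when group labels are present the mean posterior mass falling outside
    each site's dominant group is reported (and logged above 1%).
    """
    params = params or HmmParams()
    typed_idx = _match_typed_sites(panel, targets)
    cm_all = panel.cm_positions(require=True)
    cm_typed = cm_all[typed_idx]
    A = panel.haplotypes  # (S, K)
    K = A.shape[1]
    S = panel.n_sites
    T = len(typed_idx)
    M_total = targets.n_haplotypes
    perm = partner_permutation(K)
    A_f = A.astype(float)
    A_perm = A_f[:, perm]

    typed_mask = np.zeros(S, dtype=bool)
    typed_mask[typed_idx] = True

    # untyped sites grouped by flanking typed interval
    left_of = np.searchsorted(typed_idx, np.arange(S), side="right") - 1
    rho = np.empty((M_total, S))
    pi = np.empty((M_total, S))

    # interval weights on the genetic map
    lo = np.clip(left_of, 0, T - 1)
    hi = np.clip(left_of + 1, 0, T - 1)
    span = cm_typed[hi] - cm_typed[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        w_all = np.where(span > 0, (cm_all - cm_typed[lo]) / np.where(span > 0, span, 1.0), 0.5)
    w_all = np.clip(w_all, 0.0, 1.0)
    w_all[left_of < 0] = 1.0  # before first typed site: use first (right) only
    w_all[left_of >= T - 1] = 0.0  # after last typed site: use last (left) only

    group_cols = panel.haplotype_group_labels()
    group_names: list[str] = []
    group_sums = None
    cross_sum = 0.0
    if group_cols is not None:
        group_names = sorted(set(group_cols))
        onehot = np.stack([(group_cols == g).astype(float) for g in group_names], axis=1)
        group_sums = np.zeros(len(group_names))

    panel_typed = A[typed_idx]
    tgt = targets.haplotypes.T  # (M, T)

    chunk = max(1, int(chunk_elems / max(1, T * K)))
    for start in range(0, M_total, chunk):
        stop = min(M_total, start + chunk)
        post = forward_backward_batch(tgt[start:stop], panel_typed, cm_typed, params)
        # typed sites: direct application of each posterior row (batched over T)
        pt = post.transpose(1, 0, 2)  # (T, m, K)
        rho[start:stop, typed_idx] = (pt @ A_f[typed_idx][:, :, None])[:, :, 0].T
        pi[start:stop, typed_idx] = (pt @ A_perm[typed_idx][:, :, None])[:, :, 0].T
        # untyped: interpolate between flanking typed posteriors
        for t in range(-1, T):
            sel = np.flatnonzero((left_of == t) & ~typed_mask)
            if sel.size == 0:
                continue
            tl = max(t, 0)
            tr = min(t + 1, T - 1)
            Pl = post[:, tl, :]  # (m, K)
            Pr = post[:, tr, :]
            w = w_all[sel][None, :]
            rl = Pl @ A_f[sel].T
            rr = Pr @ A_f[sel].T
            rho[start:stop, sel] = (1.0 - w) * rl + w * rr
            pl = Pl @ A_perm[sel].T
            pr = Pr @ A_perm[sel].T
            pi[start:stop, sel] = (1.0 - w) * pl + w * pr
        if group_sums is not None:
            m = stop - start
            gm = post.reshape(m * T, K) @ onehot  # (m*T, G)
            group_sums += gm.sum(axis=0)
            cross_sum += float((1.0 - gm.max(axis=1)).sum())

    np.clip(rho, 0.0, 1.0, out=rho)
    np.clip(pi, 0.0, 1.0, out=pi)

    group_mass = None
    cross_mass = None
    if group_sums is not None:
        total = M_total * T
        group_mass = pd.Series(group_sums / total, index=group_names, name="posterior_mass")
        cross_mass = cross_sum / total
        if cross_mass > 0.01:
            logger.info(
                "build_dosage_table: %.2f%% of posterior mass falls outside the "
                "locally dominant reference group; pseudo-controls may be "
                "imperfectly ancestry-matched",
                100 * cross_mass,
            )

    hap_ids = [f"{sid}_h{a}" for sid in targets.sample_ids for a in (1, 2)]
    return DosageTable(
        sites=panel.sites.copy(),
        rho=rho,
        pi=pi,
        typed=typed_mask,
        hap_ids=hap_ids,
        group_mass=group_mass,
        cross_group_mass=cross_mass,
    )
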