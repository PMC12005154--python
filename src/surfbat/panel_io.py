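"""Phased haplotype panel I/O, genetic maps, and panel merge/QC.

Conventions: VCF positions are 1-based externally; all in-memory indices are
0-based.  Haplotype columns ``2*i`` and ``2*i + 1`` belong to diploid
individual ``i``.  The haplotype matrix is site-major (``n_sites x 2N``) with
entry 1 meaning the ALT allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("surfbat")

SITE_COLUMNS = ["chrom", "pos", "id", "ref", "alt", "cm"]


class VcfFormatError(ValueError):
    """Raised for records violating the phased biallelic-SNV contract."""


class VcfOrderError(ValueError):
    """Raised when records are not sorted by position within a chromosome."""


@dataclass(frozen=True)
class Site:
    """A biallelic SNV with an optional cumulative genetic position."""

    chrom: str
    pos: int
    id: str
    ref: str
    alt: str
    cm: float = float("nan")

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def _empty_sites_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=object),
            "pos": pd.Series(dtype=np.int64),
            "id": pd.Series(dtype=object),
            "ref": pd.Series(dtype=object),
            "alt": pd.Series(dtype=object),
            "cm": pd.Series(dtype=float),
        }
    )


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype matrix plus site and sample metadata.

    Attributes
    ----------
    sites
        DataFrame with columns chrom, pos, id, ref, alt, cm (cm may be NaN
        until a genetic map is attached).
    haplotypes
        uint8 matrix of shape (n_sites, 2 * n_individuals); entry 1 = ALT.
    sample_ids
        One label per diploid individual.
    group_labels
        Optional per-individual ancestry/region tag.  Simulation and
        diagnostic bookkeeping only; the association test never uses it.
    """

    sites: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str]
    group_labels: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.sites = self.sites.reset_index(drop=True)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_sites, n_haps = self.haplotypes.shape if self.haplotypes.ndim == 2 else (0, 0)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D (site x haplotype)")
        if len(self.sites) != n_sites:
            raise ValueError("site table and haplotype matrix disagree on n_sites")
        if n_haps != 2 * len(self.sample_ids):
            raise ValueError("haplotype columns must number 2 per individual")
        if self.group_labels is not None and len(self.group_labels) != len(self.sample_ids):
            raise ValueError("group_labels must have one entry per individual")
        if n_sites and self.haplotypes.max(initial=0) > 1:
            raise ValueError("haplotype entries must be 0/1")
        for chrom, sub in self.sites.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise VcfOrderError(f"positions not strictly increasing on {chrom}")
            cm = sub["cm"].to_numpy(dtype=float)
            if np.all(np.isfinite(cm)) and np.any(np.diff(cm) < -1e-12):
                raise ValueError(f"cm not non-decreasing on {chrom}")

    # -- basic properties -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    def site_keys(self) -> pd.Index:
        s = self.sites
        return pd.Index(zip(s["chrom"], s["pos"], s["ref"], s["alt"]))

    def alt_frequencies(self) -> np.ndarray:
        """Per-site ALT-allele frequency over the panel haplotypes."""
        return self.haplotypes.mean(axis=1)

    def cm_positions(self, require: bool = False) -> np.ndarray:
        cm = self.sites["cm"].to_numpy(dtype=float)
        if require and not np.all(np.isfinite(cm)):
            raise ValueError("genetic positions missing; attach a genetic map first")
        return cm

    def haplotype_group_labels(self) -> Optional[np.ndarray]:
        """Group label per haplotype column (labels are per individual)."""
        if self.group_labels is None:
            return None
        return np.repeat(np.asarray(self.group_labels, dtype=object), 2)

    # -- subsetting -------------------------------------------------------
    def subset_sites(self, index: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return HaplotypePanel(
            sites=self.sites.iloc[index].reset_index(drop=True),
            haplotypes=self.haplotypes[index],
            sample_ids=list(self.sample_ids),
            group_labels=None if self.group_labels is None else list(self.group_labels),
        )

    def subset_individuals(self, index: Sequence[int] | np.ndarray) -> "HaplotypePanel":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        cols = np.empty(2 * len(index), dtype=np.int64)
        cols[0::2] = 2 * index
        cols[1::2] = 2 * index + 1
        return HaplotypePanel(
            sites=self.sites.copy(),
            haplotypes=self.haplotypes[:, cols],
            sample_ids=[self.sample_ids[i] for i in index],
            group_labels=None
            if self.group_labels is None
            else [self.group_labels[i] for i in index],
        )


@dataclass
class TargetHaplotypes:
    """Case haplotypes observed at a subset of panel sites (the array design)."""

    typed_sites: pd.DataFrame
    haplotypes: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.typed_sites = self.typed_sites.reset_index(drop=True)
        if self.haplotypes.shape[0] != len(self.typed_sites):
            raise ValueError("typed site table and matrix disagree")
        if self.haplotypes.shape[1] != 2 * len(self.sample_ids):
            raise ValueError("haplotype columns must number 2 per individual")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[1]

    def site_keys(self) -> pd.Index:
        s = self.typed_sites
        return pd.Index(zip(s["chrom"], s["pos"], s["ref"], s["alt"]))


# ---------------------------------------------------------------------------
# Genetic maps
# ---------------------------------------------------------------------------


@dataclass
class GeneticMap:
    """Monotone bp -> cumulative-cM mapping per chromosome.

    ``anchors`` maps chromosome label to an (n, 2) float array of
    (position, cM) pairs, strictly increasing in position and non-decreasing
    in cM.  The key ``None`` acts as a wildcard used for single-chromosome
    map files that do not name their chromosome.
    """

    anchors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, arr in self.anchors.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"need >=2 (pos, cM) anchors for {chrom}")
            if np.any(np.diff(arr[:, 0]) <= 0):
                raise ValueError(f"anchor positions not strictly increasing for {chrom}")
            if np.any(np.diff(arr[:, 1]) < 0):
                raise ValueError(f"anchor cM not monotone for {chrom}")
            self.anchors[chrom] = arr

    def _anchors_for(self, chrom: str) -> np.ndarray:
        if chrom in self.anchors:
            return self.anchors[chrom]
        if None in self.anchors:
            return self.anchors[None]
        raise KeyError(f"chromosome {chrom!r} absent from genetic map")

    def interpolate(self, chrom: str, positions: Sequence[int] | np.ndarray) -> np.ndarray:
        """Piecewise-linear interpolation of cumulative cM at base positions.

        Positions outside the anchor range are extrapolated at the nearest
        flanking interval's local recombination rate, floored at 0 cM/Mb.
        """
        arr = self._anchors_for(chrom)
        pos = np.asarray(positions, dtype=float)
        cm = np.interp(pos, arr[:, 0], arr[:, 1])
        # extrapolation beyond the anchors
        left_rate = max((arr[1, 1] - arr[0, 1]) / (arr[1, 0] - arr[0, 0]), 0.0)
        right_rate = max((arr[-1, 1] - arr[-2, 1]) / (arr[-1, 0] - arr[-2, 0]), 0.0)
        below = pos < arr[0, 0]
        above = pos > arr[-1, 0]
        cm[below] = arr[0, 1] + (pos[below] - arr[0, 0]) * left_rate
        cm[above] = arr[-1, 1] + (pos[above] - arr[-1, 0]) * right_rate
        return cm


def read_genetic_map(path: str, chrom: Optional[str] = None) -> GeneticMap:
    """Read a genetic map in HapMap (3-column) or PLINK (4-column) dialect.

    The dialect is auto-detected from the column count:

    * 3 columns: ``pos  rate(cM/Mb)  cumulative_cM`` (HapMap style; the
      chromosome is taken from ``chrom`` or treated as a wildcard),
    * 4 columns: ``chrom  id  cM  pos`` (PLINK .map style).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            rows.append(parts)
    if not rows:
        raise ValueError(f"empty genetic map: {path}")
    ncol = len(rows[0])
    # tolerate a header line of non-numeric fields
    def _is_number(s: str) -> bool:
        try:
            float(s)
            return True
        except ValueError:
            return False

    anchors: dict = {}
    if ncol == 3:
        body = [r for r in rows if _is_number(r[0])]
        arr = np.array([[float(r[0]), float(r[2])] for r in body])
        anchors[chrom] = arr[np.argsort(arr[:, 0])]
    elif ncol == 4:
        body = [r for r in rows if _is_number(r[3])]
        for c in sorted({r[0] for r in body}):
            sub = np.array([[float(r[3]), float(r[2])] for r in body if r[0] == c])
            anchors[c] = sub[np.argsort(sub[:, 0])]
    else:
        raise ValueError(f"unrecognized genetic-map dialect ({ncol} columns)")
    return GeneticMap(anchors=anchors)


def attach_genetic_map(panel: HaplotypePanel, gmap: GeneticMap) -> HaplotypePanel:
    """Return a copy of ``panel`` with cumulative cM set for every site."""
    sites = panel.sites.copy()
    cm = np.empty(len(sites), dtype=float)
    for chrom, sub in sites.groupby("chrom", sort=False):
        cm[sub.index.to_numpy()] = gmap.interpolate(chrom, sub["pos"].to_numpy())
    sites["cm"] = cm
    return HaplotypePanel(
        sites=sites,
        haplotypes=panel.haplotypes,
        sample_ids=list(panel.sample_ids),
        group_labels=None if panel.group_labels is None else list(panel.group_labels),
    )


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def _parse_region(region: str):
    if ":" not in region:
        return region, None, None
    chrom, span = region.split(":", 1)
    start, end = span.split("-", 1)
    return chrom, int(start), int(end)


def read_phased_vcf(
    path: str,
    region: Optional[str] = None,
    strict: bool = True,
) -> HaplotypePanel:
    """Read a phased VCF into a :class:`HaplotypePanel`.

    Multiallelic and non-SNV records are always dropped (with a logged
    count).  Records carrying unphased or missing genotypes raise
    :class:`VcfFormatError` in strict mode and are skipped otherwise.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    sample_ids = list(vcf.samples)
    want = _parse_region(region) if region else None

    chroms: list[str] = []
    poss: list[int] = []
    ids: list[str] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_skip_shape = 0
    n_skip_phase = 0
    last: dict = {}

    for var in vcf:
        if want is not None:
            c, s, e = want
            if var.CHROM != c:
                continue
            if s is not None and not (s <= var.POS <= e):
                continue
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skip_shape += 1
            continue
        gts = np.asarray(var.genotypes)  # (n_samples, 3): a0, a1, phased
        bad = (gts[:, 0] < 0) | (gts[:, 1] < 0) | (gts[:, 2] == 0)
        if bad.any():
            if strict:
                raise VcfFormatError(
                    f"unphased or missing genotype at {var.CHROM}:{var.POS} "
                    f"(sample {sample_ids[int(np.flatnonzero(bad)[0])]})"
                )
            n_skip_phase += 1
            continue
        prev = last.get(var.CHROM)
        if prev is not None and var.POS <= prev:
            raise VcfOrderError(f"unsorted VCF at {var.CHROM}:{var.POS}")
        last[var.CHROM] = var.POS
        row = np.empty(2 * len(sample_ids), dtype=np.uint8)
        row[0::2] = gts[:, 0]
        row[1::2] = gts[:, 1]
        rows.append(row)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ids.append(var.ID or ".")
        refs.append(var.REF)
        alts.append(var.ALT[0])
    vcf.close()

    if n_skip_shape or n_skip_phase:
        logger.info(
            "read_phased_vcf(%s): skipped %d non-biallelic-SNV and %d "
            "unphased/missing records",
            path,
            n_skip_shape,
            n_skip_phase,
        )
    if rows:
        sites = pd.DataFrame(
            {
                "chrom": chroms,
                "pos": np.asarray(poss, dtype=np.int64),
                "id": ids,
                "ref": refs,
                "alt": alts,
                "cm": np.nan,
            }
        )
        haps = np.vstack(rows)
    else:
        sites = _empty_sites_frame()
        haps = np.zeros((0, 2 * len(sample_ids)), dtype=np.uint8)
    panel = HaplotypePanel(sites=sites, haplotypes=haps, sample_ids=sample_ids)
    panel.skipped_records = {"non_snv": n_skip_shape, "unphased": n_skip_phase}  # type: ignore[attr-defined]
    return panel


def write_phased_vcf(panel: HaplotypePanel, path: str) -> None:
    """Write ``panel`` as a phased VCF (bgzipped when ``path`` ends in .gz)."""
    gz = str(path).endswith(".gz")
    text_path = str(path)[:-3] if gz else str(path)
    contigs = list(dict.fromkeys(panel.sites["chrom"]))
    with open(text_path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=surfbat\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            out.write(f"##contig=<ID={c}>\n")
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        H = panel.haplotypes
        s = panel.sites
        for j in range(panel.n_sites):
            row = H[j]
            gts = "\t".join(
                f"{row[2 * i]}|{row[2 * i + 1]}" for i in range(panel.n_individuals)
            )
            out.write(
                f"{s.chrom.iat[j]}\t{s.pos.iat[j]}\t{s.id.iat[j]}\t"
                f"{s.ref.iat[j]}\t{s.alt.iat[j]}\t.\t.\t.\tGT\t{gts}\n"
            )
    if gz:
        import pysam

        pysam.tabix_compress(text_path, str(path), force=True)
        import os

        os.remove(text_path)


# ---------------------------------------------------------------------------
# Panel merge and Fst QC
# ---------------------------------------------------------------------------


def hudson_fst(p1, n1, p2, n2):
    """Per-site Hudson Fst estimate (Bhatia-style ratio form).

    ``[(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] /
    [p1(1-p2) + p2(1-p1)]``; NaN where the denominator is zero (both panels
    monomorphic for the same allele).  Accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any(np.asarray(n1) < 2) or np.any(np.asarray(n2) < 2):
        raise ValueError("hudson_fst requires at least 2 haplotypes per panel")
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return float(out) if out.ndim == 0 else out


@dataclass
class FstFilterResult:
    """Output of :func:`fst_outlier_filter` on the shared-site set."""

    keep: np.ndarray  # bool mask over shared sites
    table: pd.DataFrame  # chrom, pos, ref, alt, fst, excluded
    threshold: float
    mean: float
    sd: float

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "mean_fst": self.mean,
            "sd_fst": self.sd,
            "n_shared": int(len(self.keep)),
            "n_excluded": int((~self.keep).sum()),
        }


def _shared_site_indices(panelA: HaplotypePanel, panelB: HaplotypePanel):
    keysA = panelA.site_keys()
    keysB = panelB.site_keys()
    common = keysA.intersection(keysB)
    if len(common) == 0:
        raise ValueError("panels share no sites")
    ia = keysA.get_indexer(common)
    ib = keysB.get_indexer(common)
    order = np.argsort(ia)
    return ia[order], ib[order]


def fst_outlier_filter(panelA: HaplotypePanel, panelB: HaplotypePanel) -> FstFilterResult:
    """Flag shared sites whose Hudson Fst exceeds mean + 6 SD.

    The mean and SD are taken over sites where the estimator is defined;
    exclusion uses a strict inequality, so a degenerate spread (SD = 0)
    excludes nothing.
    """
    ia, ib = _shared_site_indices(panelA, panelB)
    pA = panelA.haplotypes[ia].mean(axis=1)
    pB = panelB.haplotypes[ib].mean(axis=1)
    fst = hudson_fst(pA, panelA.n_haplotypes, pB, panelB.n_haplotypes)
    fst = np.atleast_1d(fst)
    finite = np.isfinite(fst)
    mean = float(np.mean(fst[finite])) if finite.any() else float("nan")
    sd = float(np.std(fst[finite], ddof=0)) if finite.any() else float("nan")
    threshold = mean + 6.0 * sd
    keep = ~(finite & (fst > threshold))
    table = panelA.sites.iloc[ia][["chrom", "pos", "ref", "alt"]].reset_index(drop=True)
    table["fst"] = fst
    table["excluded"] = ~keep
    if (~keep).any():
        logger.info(
            "fst_outlier_filter: excluded %d/%d sites above Fst %.4g",
            int((~keep).sum()),
            len(keep),
            threshold,
        )
    return FstFilterResult(keep=keep, table=table, threshold=threshold, mean=mean, sd=sd)


def merge_panels(panelA: HaplotypePanel, panelB: HaplotypePanel) -> HaplotypePanel:
    """Merge two panels on the exact (chrom, pos, ref, alt) intersection.

    Haplotype columns are concatenated A then B.  Sites present at the same
    position with mismatched alleles are dropped (never flipped or swapped)
    and the count is logged.
    """
    chromsA = set(panelA.sites["chrom"])
    chromsB = set(panelB.sites["chrom"])
    if chromsA and chromsB and chromsA != chromsB:
        raise ValueError("merge_panels requires panels on the same chromosome(s)")
    ia, ib = _shared_site_indices(panelA, panelB)
    # report positions shared but allele-mismatched
    posA = set(zip(panelA.sites["chrom"], panelA.sites["pos"]))
    posB = set(zip(panelB.sites["chrom"], panelB.sites["pos"]))
    n_pos_shared = len(posA & posB)
    if n_pos_shared > len(ia):
        logger.info(
            "merge_panels: dropped %d positions with mismatched ref/alt",
            n_pos_shared - len(ia),
        )
    sites = panelA.sites.iloc[ia].reset_index(drop=True)
    haps = np.hstack([panelA.haplotypes[ia], panelB.haplotypes[ib]])
    labelsA = panelA.group_labels
    labelsB = panelB.group_labels
    if labelsA is None and labelsB is None:
        labels = None
    else:
        labels = list(labelsA or [None] * panelA.n_individuals) + list(
            labelsB or [None] * panelB.n_individuals
        )
    return HaplotypePanel(
        sites=sites,
        haplotypes=haps,
        sample_ids=list(panelA.sample_ids) + list(panelB.sample_ids),
        group_labels=labels,
    )
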