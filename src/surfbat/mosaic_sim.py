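"""Mosaic-haplotype simulation for calibration and power studies.

Case haplotypes are built as cM-scale mosaics of a phased panel: tile
breakpoints follow a Poisson process on the genetic map (exponential tile
lengths), each tile's source group is drawn from configurable weights and
the source haplotype uniformly within that group, and alleles are copied
verbatim.  The module also generates the synthetic two/three-group founder
panels the scenarios run against, injects local-ancestry-only and allelic
association signals, and designs array-like typed-site subsets (MAF filter +
LD thinning + random draw).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import HaplotypePanel, TargetHaplotypes, write_phased_vcf

logger = logging.getLogger("surfbat")


@dataclass(frozen=True)
class MosaicSpec:
    """Mosaic process parameters.

    tile_cm
        Mean tile length in cM (exponential gaps between breakpoints).
    group_weights
        Probability of drawing each tile's source from a given panel group;
        must sum to 1 over groups present in the panel.
    seed
        RNG seed used when no generator is supplied.
    pool_size
        Number of haplotypes to pre-simulate when drawing from a pool.
    """

    tile_cm: float = 10.0
    group_weights: dict = field(default_factory=dict)
    seed: Optional[int] = None
    pool_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.tile_cm <= 0:
            raise ValueError("tile_cm must be positive")
        if self.group_weights:
            w = np.array(list(self.group_weights.values()), dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("group weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class Tile:
    start_cm: float
    end_cm: float
    group: str
    source_hap: int


@dataclass
class TileTrack:
    """Contiguous, chromosome-covering record of one mosaic haplotype."""

    tiles: list[Tile]

    def group_at(self, cm: float) -> str:
        for t in self.tiles:
            if t.start_cm <= cm < t.end_cm:
                return t.group
        return self.tiles[-1].group

    def source_at(self, cm: float) -> int:
        for t in self.tiles:
            if t.start_cm <= cm < t.end_cm:
                return t.source_hap
        return self.tiles[-1].source_hap

    def group_fraction(self, group: str) -> float:
        total = sum(t.end_cm - t.start_cm for t in self.tiles)
        part = sum(t.end_cm - t.start_cm for t in self.tiles if t.group == group)
        return part / total if total > 0 else 0.0


def _group_columns(panel: HaplotypePanel) -> dict[str, np.ndarray]:
    labels = panel.haplotype_group_labels()
    if labels is None:
        raise ValueError("panel carries no group labels")
    return {g: np.flatnonzero(labels == g) for g in dict.fromkeys(labels)}


def _draw_breakpoints(cm_lo: float, cm_hi: float, tile_cm: float, rng) -> np.ndarray:
    """Tile end positions covering (cm_lo, cm_hi]; last end exceeds cm_hi."""
    ends = []
    x = cm_lo
    while x <= cm_hi:
        x += rng.exponential(tile_cm)
        ends.append(x)
    ends[-1] = max(ends[-1], cm_hi + 1e-9)
    return np.asarray(ends)


def simulate_mosaic_haplotype(
    panel: HaplotypePanel,
    spec: MosaicSpec,
    rng: np.random.Generator,
):
    """One mosaic haplotype: copied alleles and its tile truth track.

    Breakpoints are a Poisson process at rate 1/tile_cm on the cM axis; each
    tile draws its source group from ``spec.group_weights`` and a source
    haplotype uniformly within the group; alleles are copied verbatim (no
    mutation; imperfection is modelled downstream by the HMM's eps).
    """
    cm = panel.cm_positions(require=True)
    cols = _group_columns(panel)
    groups = list(spec.group_weights) if spec.group_weights else list(cols)
    weights = (
        np.array([spec.group_weights[g] for g in groups])
        if spec.group_weights
        else np.full(len(groups), 1.0 / len(cols))
    )
    for g in groups:
        if g not in cols or cols[g].size == 0:
            raise ValueError(f"group {g!r} has no haplotypes in the panel")
    cm_lo, cm_hi = float(cm[0]), float(cm[-1])
    ends = _draw_breakpoints(cm_lo, cm_hi, spec.tile_cm, rng)
    n_tiles = len(ends)
    g_idx = rng.choice(len(groups), size=n_tiles, p=weights)
    sources = np.array([cols[groups[g]][rng.integers(cols[groups[g]].size)] for g in g_idx])
    tile_of_site = np.searchsorted(ends, cm, side="right")
    tile_of_site = np.minimum(tile_of_site, n_tiles - 1)
    alleles = panel.haplotypes[np.arange(panel.n_sites), sources[tile_of_site]]
    starts = np.concatenate([[cm_lo], ends[:-1]])
    track = TileTrack(
        tiles=[
            Tile(float(s), float(e), groups[g], int(h))
            for s, e, g, h in zip(starts, ends, g_idx, sources)
        ]
    )
    return alleles, track


def simulate_pool(
    panel: HaplotypePanel,
    n_haplotypes: int,
    spec: MosaicSpec,
    rng: Optional[np.random.Generator] = None,
):
    """Pre-simulate a pool of mosaic haplotypes: ((n, S) alleles, tracks)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    alleles = np.empty((n_haplotypes, panel.n_sites), dtype=np.uint8)
    tracks: list[TileTrack] = []
    for i in range(n_haplotypes):
        alleles[i], track = simulate_mosaic_haplotype(panel, spec, rng)
        tracks.append(track)
    return alleles, tracks


def simulate_case_cohort(
    panel: HaplotypePanel,
    n_cases: int,
    spec: MosaicSpec,
    rng: Optional[np.random.Generator] = None,
):
    """Simulate 2*n_cases mosaic case haplotypes at all panel sites.

    Deterministic given the spec's seed (or the supplied generator).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    alleles, tracks = simulate_pool(panel, 2 * n_cases, spec, rng)
    targets = TargetHaplotypes(
        typed_sites=panel.sites.copy(),
        haplotypes=alleles.T,
        sample_ids=[f"CASE{i + 1:04d}" for i in range(n_cases)],
    )
    return targets, tracks


# ---------------------------------------------------------------------------
# Signal injection
# ---------------------------------------------------------------------------


def inject_local_ancestry_signal(
    tracks: Sequence[TileTrack],
    focal_cm: float,
    n_group_a: int,
    n_group_b: int,
    group_a: str,
    group_b: str,
    rng: np.random.Generator,
) -> np.ndarray:
    """Select pool haplotypes by the group of the tile overlapping a locus.

    Exactly ``n_group_a`` haplotypes whose tile at ``focal_cm`` came from
    ``group_a`` and ``n_group_b`` from ``group_b`` are drawn without
    replacement; no allele constraint is imposed, so the induced signal is
    purely one of local ancestry.
    """
    groups_at = np.array([t.group_at(focal_cm) for t in tracks])
    cand_a = np.flatnonzero(groups_at == group_a)
    cand_b = np.flatnonzero(groups_at == group_b)
    if cand_a.size < n_group_a or cand_b.size < n_group_b:
        raise ValueError(
            f"pool too small at focal locus: need {n_group_a} {group_a} "
            f"(have {cand_a.size}) and {n_group_b} {group_b} (have {cand_b.size})"
        )
    sel_a = rng.choice(cand_a, size=n_group_a, replace=False)
    sel_b = rng.choice(cand_b, size=n_group_b, replace=False)
    return rng.permutation(np.concatenate([sel_a, sel_b]))


def inject_allelic_signal(
    pool_alleles: np.ndarray,
    signal_site: int,
    n_carriers: int,
    n_noncarriers: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Select pool haplotypes by carrier status at one site.

    Carriers of the ALT allele at ``signal_site`` may come from any source
    group, so the injected allelic signal is naturally confounded with local
    ancestry whenever the groups differ in frequency at that site.
    """
    carrier = pool_alleles[:, signal_site] == 1
    cand_c = np.flatnonzero(carrier)
    cand_n = np.flatnonzero(~carrier)
    if cand_c.size < n_carriers or cand_n.size < n_noncarriers:
        raise ValueError(
            f"pool too small at signal site: need {n_carriers} carriers "
            f"(have {cand_c.size}) and {n_noncarriers} noncarriers (have {cand_n.size})"
        )
    sel_c = rng.choice(cand_c, size=n_carriers, replace=False)
    sel_n = rng.choice(cand_n, size=n_noncarriers, replace=False)
    return rng.permutation(np.concatenate([sel_c, sel_n]))


# ---------------------------------------------------------------------------
# Array design and site filters
# ---------------------------------------------------------------------------


def design_array_sites(
    panel: HaplotypePanel,
    maf_min: float = 0.1,
    r2_max: float = 0.8,
    n_sites: int = 5000,
    rng: Optional[np.random.Generator] = None,
    window_cm: float = 1.0,
) -> np.ndarray:
    """Array-like typed-site subset: MAF filter, LD thinning, random draw.

    Greedy left-to-right thinning drops any site whose haplotype correlation
    r^2 with the last retained site (within ``window_cm``) exceeds
    ``r2_max``; the surviving candidates are then sampled uniformly down to
    ``n_sites`` (all are returned, with a warning, when fewer remain).
    """
    rng = rng if rng is not None else np.random.default_rng()
    freq = panel.alt_frequencies()
    maf = np.minimum(freq, 1.0 - freq)
    cand = np.flatnonzero(maf >= maf_min)
    cm = panel.cm_positions()
    H = panel.haplotypes
    kept: list[int] = []
    last = -1
    for j in cand:
        if last < 0 or (np.isfinite(cm[j]) and cm[j] - cm[last] > window_cm):
            kept.append(j)
            last = j
            continue
        x = H[j].astype(float)
        y = H[last].astype(float)
        vx = x.var()
        vy = y.var()
        if vx == 0 or vy == 0:
            continue
        r = ((x * y).mean() - x.mean() * y.mean()) / np.sqrt(vx * vy)
        if r * r > r2_max:
            continue
        kept.append(j)
        last = j
    kept_arr = np.asarray(kept, dtype=np.int64)
    if kept_arr.size > n_sites:
        kept_arr = np.sort(rng.choice(kept_arr, size=n_sites, replace=False))
    elif kept_arr.size < n_sites:
        logger.warning(
            "design_array_sites: only %d candidates after filtering (requested %d)",
            kept_arr.size,
            n_sites,
        )
    return kept_arr


def frequency_window_filter(panel: HaplotypePanel, lo: float = 0.05, hi: float = 0.95) -> np.ndarray:
    """Mask of sites whose ALT (derived) frequency lies in [lo, hi]."""
    freq = panel.alt_frequencies()
    return (freq >= lo) & (freq <= hi)


def decimate_sites(n_sites: int, k: int) -> np.ndarray:
    """Every k-th site index (0, k, 2k, ...)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return np.arange(0, n_sites, k, dtype=np.int64)


# ---------------------------------------------------------------------------
# Founder panel generation
# ---------------------------------------------------------------------------


def generate_founder_panel(
    n_individuals: dict[str, int],
    n_sites: int,
    length_cm: float = 100.0,
    bp_per_cm: int = 1_000_000,
    fst: float = 0.15,
    n_founders: int = 40,
    founder_tile_cm: float = 0.5,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "1",
) -> HaplotypePanel:
    """Synthetic multi-group phased panel with LD, at a constant map rate.

    Group allele frequencies follow the Balding-Nichols model around a
    shared ancestral frequency (Uniform(0.05, 0.95)) at differentiation
    ``fst``; each group's haplotypes are short-tile mosaics of ``n_founders``
    founder haplotypes, which creates within-group LD and haplotype sharing.
    Both haplotypes of an individual come from the same group, so partner
    haplotypes are ancestry-matched by construction.
    """
    rng = rng if rng is not None else np.random.default_rng()
    length_bp = int(length_cm * bp_per_cm)
    pos = np.sort(rng.choice(np.arange(1, length_bp + 1), size=n_sites, replace=False))
    cm = pos / bp_per_cm
    p0 = rng.uniform(0.05, 0.95, size=n_sites)
    shape = (1.0 - fst) / fst
    sites = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "id": [f"snp{j + 1}" for j in range(n_sites)],
            "ref": "A",
            "alt": "G",
            "cm": cm,
        }
    )
    blocks = []
    sample_ids: list[str] = []
    labels: list[str] = []
    for group, n_ind in n_individuals.items():
        pg = rng.beta(np.maximum(p0 * shape, 1e-3), np.maximum((1.0 - p0) * shape, 1e-3))
        founders = (rng.random((n_founders, n_sites)) < pg).astype(np.uint8)
        haps = np.empty((2 * n_ind, n_sites), dtype=np.uint8)
        for h in range(2 * n_ind):
            ends = _draw_breakpoints(float(cm[0]), float(cm[-1]), founder_tile_cm, rng)
            src = rng.integers(n_founders, size=len(ends))
            tile = np.minimum(np.searchsorted(ends, cm, side="right"), len(ends) - 1)
            haps[h] = founders[src[tile], np.arange(n_sites)]
        blocks.append(haps.T)
        sample_ids += [f"{group}{i + 1:04d}" for i in range(n_ind)]
        labels += [group] * n_ind
    return HaplotypePanel(
        sites=sites,
        haplotypes=np.hstack(blocks),
        sample_ids=sample_ids,
        group_labels=labels,
    )


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

SCENARIO_NAMES = (
    "null",
    "ancestry_signal",
    "allelic_signal",
    "admixed_null",
    "small_panel_inflation",
)


@dataclass
class ScenarioBundle:
    """Fully reproducible simulation scenario.

    ``panel`` is the reference panel the scan should run against
    (``alt_panel`` carries the contrasting panel for the inflation
    scenario); ``targets`` holds the case haplotypes at typed sites only;
    ``case_alleles`` keeps the full-site truth matrix (haplotype x site).
    """

    name: str
    scale: float
    seed: int
    panel: HaplotypePanel
    targets: TargetHaplotypes
    case_alleles: np.ndarray
    typed_index: np.ndarray
    tracks: list
    truth: dict
    config: dict
    alt_panel: Optional[HaplotypePanel] = None

    def tracks_frame(self) -> pd.DataFrame:
        rows = []
        for h, tr in enumerate(self.tracks):
            for t in tr.tiles:
                rows.append((h, t.start_cm, t.end_cm, t.group, t.source_hap))
        return pd.DataFrame(
            rows, columns=["haplotype", "start_cm", "end_cm", "group", "source_hap"]
        )

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_phased_vcf(self.panel, os.path.join(out_dir, "reference.vcf"))
        if self.alt_panel is not None:
            write_phased_vcf(self.alt_panel, os.path.join(out_dir, "reference_alt.vcf"))
        tpanel = HaplotypePanel(
            sites=self.targets.typed_sites.copy(),
            haplotypes=self.targets.haplotypes,
            sample_ids=self.targets.sample_ids,
        )
        write_phased_vcf(tpanel, os.path.join(out_dir, "targets.vcf"))
        self.tracks_frame().to_csv(
            os.path.join(out_dir, "truth.tsv"), sep="\t", index=False, float_format="%.6f"
        )
        pd.DataFrame(
            {"sample": self.panel.sample_ids, "group": self.panel.group_labels}
        ).to_csv(os.path.join(out_dir, "groups.tsv"), sep="\t", index=False)
        # PLINK-style 4-column map (chrom, id, cM, pos) from evenly spaced anchors
        s = self.panel.sites
        idx = np.unique(np.linspace(0, len(s) - 1, 11).astype(int))
        with open(os.path.join(out_dir, "map.txt"), "w") as fh:
            for j in idx:
                fh.write(f"{s.chrom.iat[j]}\tanchor{j}\t{s.cm.iat[j]:.6f}\t{s.pos.iat[j]}\n")
        cfg = dict(self.config)
        cfg["truth"] = self.truth
        with open(os.path.join(out_dir, "config.json"), "w") as fh:
            json.dump(cfg, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")


def _scaled(x: float, scale: float, floor: int) -> int:
    return max(floor, int(round(x * scale)))


def scenario(name: str, scale: float = 1.0, seed: int = 0) -> ScenarioBundle:
    """Build one of the named study designs at a given scale.

    The defaults reproduce the study conditions of the simulation designs
    the tool is validated on: 50/50 two-group mosaics with 10 cM tiles for
    the null; a 650:250-composition local-ancestry locus and a 500:400
    carrier excess at a common variant for the signal designs (450 cases
    drawn from a pre-simulated pool); a three-way 1/6-1/3-1/2 admixture null
    with mean tile length 100/12 cM (the expected segment length 12
    generations after admixture); and a 5 cM European-mosaic design scanned
    against well-matched versus mismatched reference panels.
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    n_sites_raw = _scaled(6000, scale, 80)
    n_typed = _scaled(1000, scale, 40)
    config: dict = {"name": name, "scale": scale, "seed": seed, "n_sites_raw": n_sites_raw}
    truth: dict = {}
    alt_panel = None

    if name in ("null", "ancestry_signal", "allelic_signal"):
        groups = {"AFR": _scaled(250, scale, 8), "EUR": _scaled(250, scale, 8)}
        base = generate_founder_panel(groups, n_sites_raw, rng=rng)
        spec = MosaicSpec(tile_cm=10.0, group_weights={"AFR": 0.5, "EUR": 0.5})
    elif name == "admixed_null":
        groups = {"AFR": _scaled(170, scale, 6), "EUR": _scaled(170, scale, 6), "ASIA": _scaled(170, scale, 6)}
        base = generate_founder_panel(groups, n_sites_raw, rng=rng)
        spec = MosaicSpec(
            tile_cm=100.0 / 12.0,
            group_weights={"AFR": 1.0 / 6.0, "EUR": 1.0 / 3.0, "ASIA": 1.0 / 2.0},
        )
    else:  # small_panel_inflation
        groups = {"EUR": _scaled(1000, scale, 30), "AFR": _scaled(475, scale, 15), "ASIA": _scaled(475, scale, 15)}
        base = generate_founder_panel(groups, n_sites_raw, rng=rng)
        spec = MosaicSpec(tile_cm=5.0, group_weights={"EUR": 1.0})

    keep = frequency_window_filter(base, 0.05, 0.95)
    panel = base.subset_sites(keep)
    typed_index = design_array_sites(panel, maf_min=0.1, r2_max=0.8, n_sites=n_typed, rng=rng)
    config["n_sites"] = int(panel.n_sites)
    config["n_typed"] = int(typed_index.size)
    config["tile_cm"] = spec.tile_cm
    config["group_weights"] = spec.group_weights
    cm = panel.cm_positions()

    if name in ("null", "admixed_null"):
        n_cases = _scaled(200, scale, 4)
        case_alleles, tracks = simulate_pool(panel, 2 * n_cases, spec, rng)
    elif name == "ancestry_signal":
        n_cases = _scaled(450, scale, 6)
        n_sel = 2 * n_cases
        pool_n = 4 * n_sel
        pool, pool_tracks = simulate_pool(panel, pool_n, spec, rng)
        focal_cm = float(cm[np.argmin(np.abs(cm - (cm[0] + cm[-1]) / 2.0))])
        focal_pos = int(panel.sites.pos.iloc[int(np.argmin(np.abs(cm - focal_cm)))])
        n_a = int(round(n_sel * 650.0 / 900.0))
        n_b = n_sel - n_a
        sel = inject_local_ancestry_signal(pool_tracks, focal_cm, n_a, n_b, "EUR", "AFR", rng)
        case_alleles = pool[sel]
        tracks = [pool_tracks[i] for i in sel]
        truth = {
            "focal_pos": focal_pos,
            "focal_cm": focal_cm,
            "n_focal_EUR": n_a,
            "n_focal_AFR": n_b,
        }
    elif name == "allelic_signal":
        n_cases = _scaled(450, scale, 6)
        n_sel = 2 * n_cases
        pool_n = 6 * n_sel
        pool, pool_tracks = simulate_pool(panel, pool_n, spec, rng)
        freq_g = {
            g: panel.haplotypes[:, colsg].mean(axis=1)
            for g, colsg in _group_columns(panel).items()
        }
        maf_ok = np.ones(panel.n_sites, dtype=bool)
        for f in freq_g.values():
            maf_ok &= np.minimum(f, 1.0 - f) >= 0.2
        candidates = np.flatnonzero(maf_ok)
        if candidates.size == 0:
            raise ValueError("no candidate signal site with MAF >= 0.2 in every group")
        signal_site = int(rng.choice(candidates))
        n_car = int(round(n_sel * 500.0 / 900.0))
        n_non = n_sel - n_car
        sel = inject_allelic_signal(pool, signal_site, n_car, n_non, rng)
        case_alleles = pool[sel]
        tracks = [pool_tracks[i] for i in sel]
        truth = {
            "signal_site_index": signal_site,
            "signal_pos": int(panel.sites.pos.iloc[signal_site]),
            "signal_cm": float(cm[signal_site]),
            "n_carriers": n_car,
            "n_noncarriers": n_non,
        }
    else:  # small_panel_inflation
        n_cases = _scaled(500, scale, 6)
        labels = np.asarray(panel.group_labels, dtype=object)
        eur = np.flatnonzero(labels == "EUR")
        non_eur = np.flatnonzero(labels != "EUR")
        case_alleles, tracks = simulate_pool(panel, 2 * n_cases, spec, rng)
        n_match_small = _scaled(50, scale, 2)
        n_mismatch = _scaled(950, scale, 10)
        small = rng.choice(eur, size=n_match_small, replace=False)
        mism = rng.choice(non_eur, size=min(n_mismatch, non_eur.size), replace=False)
        well_matched = panel.subset_individuals(eur)
        mixed = panel.subset_individuals(np.sort(np.concatenate([small, mism])))
        truth = {
            "n_well_matched_haplotypes": 2 * eur.size,
            "n_mixed_matched_haplotypes": 2 * int(small.size),
            "n_mixed_mismatched_haplotypes": 2 * int(mism.size),
        }
        panel, alt_panel = well_matched, mixed

    targets = TargetHaplotypes(
        typed_sites=panel.sites.iloc[typed_index].reset_index(drop=True),
        haplotypes=case_alleles[:, typed_index].T,
        sample_ids=[f"CASE{i + 1:04d}" for i in range(n_cases)],
    )
    config["n_cases"] = n_cases
    return ScenarioBundle(
        name=name,
        scale=scale,
        seed=seed,
        panel=panel,
        targets=targets,
        case_alleles=case_alleles,
        typed_index=typed_index,
        tracks=tracks,
        truth=truth,
        config=config,
        alt_panel=alt_panel,
    )
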