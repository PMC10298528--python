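"""Synthetic study worlds for end-to-end testing of the CNV-climate pipeline.

A world emulates a worldwide survey of autochthonous populations: sampling
sites grouped into a small number of geographic clusters along a latitude
gradient, a site x variable climate table (nine parameters, monthly plus
yearly means, plus elevation), structured populations, per-sample CNV
calls at a set of loci, per-sample array QC metrics, an array probe map,
and gene / QTL interval annotations.  A subset of loci is "planted": the
per-sample probability of carrying the CNV follows a logistic function of
one standardized climate variable, on top of cluster-specific offsets
that mimic population structure.  Ground truth (which loci are planted,
their target variable and slope) is recorded so downstream scans can be
scored.

The default configuration approximates the study design the pipeline is
meant for: 47 sites in 4 clusters with ~15 samples each (~700 samples).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io

__all__ = ["WorldConfig", "World", "generate_world", "write_fixtures",
           "CLIMATE_PARAMS", "climate_columns"]

# per-parameter generation: (base at 10 deg N, latitude slope per deg,
# site noise sd, seasonal amplitude, monthly noise sd, lower clip, upper clip)
CLIMATE_PARAMS: dict[str, tuple] = {
    "SUN": (0.78, -0.0060, 0.04, 0.10, 0.02, 0.02, 1.0),   # sunshine fraction
    "DTR": (14.0, -0.08, 1.0, 2.0, 0.5, 0.0, None),        # diurnal range, degC
    "REH": (55.0, 0.40, 5.0, 8.0, 2.0, 0.0, 100.0),        # relative humidity, %
    "PR": (80.0, -0.60, 15.0, 25.0, 5.0, 0.0, None),       # precipitation, mm/month
    "TMP": (26.0, -0.45, 2.0, 8.0, 1.0, None, None),       # mean temperature, degC
    "PRCV": (40.0, 0.30, 8.0, 10.0, 3.0, 0.0, None),       # precip CV, %
    "FRS": (1.0, 0.30, 2.0, 4.0, 1.0, 0.0, None),          # ground-frost days
    "WND": (3.5, 0.02, 0.5, 0.8, 0.2, 0.0, None),          # wind speed, m/s
    "RDO": (8.0, 0.12, 2.0, 3.0, 1.0, 0.0, None),          # rain days > 0.1 mm
}

# call-level copy-number class weights (CN0, CN1, CN3, CN4)
CN_CLASS_WEIGHTS = {0: 0.1207, 1: 0.5952, 3: 0.2815, 4: 0.0026}


def climate_columns() -> list[str]:
    """The 117 climate column names: 9 parameters x (12 monthly + 1 yearly)."""
    cols = []
    for p in CLIMATE_PARAMS:
        cols.extend(f"{p}_m{m:02d}" for m in range(1, 13))
        cols.append(f"{p}_yearly")
    return cols


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    ``effect_size`` is the logistic slope of planted-locus carrier
    probability on the standardized target climate variable;
    ``cluster_sd`` scales the cluster-specific logit offsets that create
    population-structure confounding.
    """

    n_sites: int = 47
    samples_per_site: int = 15
    n_clusters: int = 4
    n_cnv_loci: int = 200
    n_planted: int = 10
    effect_size: float = 1.5
    baseline_freq_range: tuple[float, float] = (0.05, 0.40)
    probe_spacing_bp: int = 10_000
    seed: int = 0
    # secondary structure of the world
    target_variable: str = "SUN_yearly"
    cluster_sd: float = 1.0
    n_chroms: int = 3
    chrom_len_bp: int = 12_000_000
    locus_len_range_bp: tuple[int, int] = (30_000, 100_000)
    coord_jitter_bp: int = 4_000
    yearly_noise: float = 0.004     # relative sd of yearly vs monthly mean
    frac_bad_samples: float = 0.05  # violate a QC threshold
    frac_bad_calls: float = 0.05    # extra calls failing the call filters
    n_genes: int = 150
    n_qtls: int = 40

    def __post_init__(self) -> None:
        counts = dict(n_sites=self.n_sites, samples_per_site=self.samples_per_site,
                      n_clusters=self.n_clusters, n_cnv_loci=self.n_cnv_loci)
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_planted < 0 or self.n_planted > self.n_cnv_loci:
            raise ValueError("n_planted must lie in [0, n_cnv_loci]")
        lo, hi = self.baseline_freq_range
        if not (0 < lo <= hi < 1):
            raise ValueError("baseline frequencies must lie in (0, 1)")
        if self.n_clusters > self.n_sites:
            raise ValueError("need at least one site per cluster")


@dataclass
class World:
    """A generated world: every table downstream stages consume, plus truth."""

    config: WorldConfig
    climate: pd.DataFrame      # site-indexed; lat/lon/elevation + 117 columns
    samples: pd.DataFrame      # sample, site, cluster
    calls: pd.DataFrame        # internal call schema (incl. locus id, '' for junk)
    sample_qc: pd.DataFrame
    probes: pd.DataFrame       # probe, chrom, pos
    genes: pd.DataFrame        # chrom, start, end, name
    qtls: pd.DataFrame         # chrom, start, end, name, ci_width_bp
    truth: pd.DataFrame        # locus, is_planted, target_variable, effect, ...

    def sample_climate(self, columns=None) -> pd.DataFrame:
        """Per-sample climate values (each sample takes its site's value)."""
        cols = list(columns) if columns is not None else self.climate.columns.tolist()
        joined = self.samples.join(self.climate[cols], on="site")
        return joined.set_index("sample")[cols]

    def genotype_matrix(self, calls: pd.DataFrame | None = None,
                        samples=None) -> pd.DataFrame:
        """Samples x loci binary CNV-state matrix (present/absent).

        Built from the locus labels carried by the world's calls; pass a
        filtered call table to restrict to QC-passing calls.  Rows cover
        all world samples unless ``samples`` is given.
        """
        calls = self.calls if calls is None else calls
        if samples is None:
            samples = self.samples["sample"].tolist()
        tagged = calls[calls["locus"] != ""]
        hit = (tagged.groupby(["sample", "locus"]).size().unstack(fill_value=0) > 0)
        return (hit.astype(np.int8)
                .reindex(index=samples, columns=self.truth["locus"], fill_value=0)
                .rename_axis(index="sample", columns=None))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _make_sites(cfg: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    clusters = np.sort(np.arange(cfg.n_sites) % cfg.n_clusters)
    lat_centers = np.linspace(8.0, 58.0, cfg.n_clusters)
    lon_centers = np.linspace(-10.0, 95.0, cfg.n_clusters)
    lat = np.clip(lat_centers[clusters] + rng.normal(0, 4.0, cfg.n_sites), -65, 65)
    lon = lon_centers[clusters] + rng.normal(0, 8.0, cfg.n_sites)
    elev = np.abs(rng.normal(500.0, 400.0, cfg.n_sites))
    return pd.DataFrame({
        "site": [f"site{i:02d}" for i in range(cfg.n_sites)],
        "cluster": clusters,
        "latitude": lat,
        "longitude": lon,
        "elevation": elev,
    }).set_index("site")


def _make_climate(cfg: WorldConfig, sites: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    n = len(sites)
    lat = sites["latitude"].to_numpy()
    data = {"latitude": lat, "longitude": sites["longitude"].to_numpy(),
            "elevation": sites["elevation"].to_numpy()}
    month_phase = np.sin(2 * np.pi * (np.arange(1, 13) - 4) / 12.0)  # peak ~July
    for p, (base, slope, site_sd, amp, msd, lo, hi) in CLIMATE_PARAMS.items():
        annual = base + slope * (lat - 10.0) + rng.normal(0, site_sd, n)
        monthly = (annual[:, None]
                   + amp * month_phase[None, :]
                   + rng.normal(0, msd, (n, 12)))
        if lo is not None or hi is not None:
            monthly = np.clip(monthly, lo, hi)
        yearly = monthly.mean(axis=1) * (1 + rng.normal(0, cfg.yearly_noise, n))
        if lo is not None or hi is not None:
            yearly = np.clip(yearly, lo, hi)
        for m in range(12):
            data[f"{p}_m{m + 1:02d}"] = monthly[:, m]
        data[f"{p}_yearly"] = yearly
    return pd.DataFrame(data, index=sites.index)[
        ["latitude", "longitude", "elevation"] + climate_columns()]


def _make_loci(cfg: WorldConfig, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = int(np.ceil(cfg.n_cnv_loci / cfg.n_chroms))
    max_len = cfg.locus_len_range_bp[1]
    slot = max(cfg.chrom_len_bp // per_chrom, max_len + 2 * cfg.coord_jitter_bp + 2)
    rows = []
    k = 0
    for c in range(cfg.n_chroms):
        chrom = f"chr{c + 1}"
        for j in range(per_chrom):
            if k >= cfg.n_cnv_loci:
                break
            length = int(rng.integers(*cfg.locus_len_range_bp))
            lo = j * slot + cfg.coord_jitter_bp + 1
            start = int(lo + rng.integers(0, max(slot - length - 2 * cfg.coord_jitter_bp, 1)))
            rows.append((f"locus{k:04d}", chrom, start, start + length - 1))
            k += 1
    loci = pd.DataFrame(rows, columns=["locus", "chrom", "start", "end"])
    del_frac = (CN_CLASS_WEIGHTS[0] + CN_CLASS_WEIGHTS[1])
    loci["polarity"] = np.where(rng.random(len(loci)) < del_frac, "del", "dup")
    lo, hi = cfg.baseline_freq_range
    loci["baseline_freq"] = rng.uniform(lo, hi, len(loci))
    return loci


def generate_world(config: WorldConfig) -> World:
    """Generate a complete world; identical config (incl. seed) is reproducible."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    sites = _make_sites(cfg, rng)
    climate = _make_climate(cfg, sites, rng)
    if cfg.target_variable not in climate.columns:
        raise ValueError(f"target variable {cfg.target_variable!r} not in climate table")

    samples = pd.DataFrame({
        "sample": [f"{s}_i{k:02d}" for s in sites.index
                   for k in range(cfg.samples_per_site)],
        "site": np.repeat(sites.index.to_numpy(), cfg.samples_per_site),
    })
    samples["cluster"] = sites.loc[samples["site"], "cluster"].to_numpy()
    n_samples = len(samples)

    loci = _make_loci(cfg, rng)
    planted_idx = rng.choice(len(loci), size=cfg.n_planted, replace=False)
    is_planted = np.zeros(len(loci), dtype=bool)
    is_planted[planted_idx] = True

    # standardized target variable per sample (site value)
    z_site = climate[cfg.target_variable]
    z = (z_site - z_site.mean()) / z_site.std(ddof=0)
    z_sample = z.loc[samples["site"]].to_numpy()

    cluster_off = rng.normal(0.0, cfg.cluster_sd, (len(loci), cfg.n_clusters))
    effects = np.where(is_planted, cfg.effect_size, 0.0)
    logit_base = np.log(loci["baseline_freq"] / (1 - loci["baseline_freq"])).to_numpy()

    # carrier probability per (locus, sample)
    logits = (logit_base[:, None]
              + cluster_off[np.arange(len(loci))[:, None], samples["cluster"].to_numpy()[None, :]]
              + effects[:, None] * z_sample[None, :])
    carrier = rng.random((len(loci), n_samples)) < _sigmoid(logits)

    # per-call class conditional on locus polarity
    p_cn1 = CN_CLASS_WEIGHTS[1] / (CN_CLASS_WEIGHTS[0] + CN_CLASS_WEIGHTS[1])
    p_cn3 = CN_CLASS_WEIGHTS[3] / (CN_CLASS_WEIGHTS[3] + CN_CLASS_WEIGHTS[4])

    li, si = np.nonzero(carrier)
    n_calls = len(li)
    jitter = rng.integers(-cfg.coord_jitter_bp, cfg.coord_jitter_bp + 1, (n_calls, 2)) \
        if cfg.coord_jitter_bp else np.zeros((n_calls, 2), dtype=int)
    starts = np.maximum(loci["start"].to_numpy()[li] + jitter[:, 0], 1)
    ends = np.maximum(loci["end"].to_numpy()[li] + jitter[:, 1], starts + 999)
    is_del = loci["polarity"].to_numpy()[li] == "del"
    u = rng.random(n_calls)
    cn = np.where(is_del, np.where(u < p_cn1, 1, 0), np.where(u < p_cn3, 3, 4))
    lengths = ends - starts + 1
    num_snps = np.maximum(
        np.round(lengths / cfg.probe_spacing_bp).astype(int)
        + rng.integers(-1, 2, n_calls), 4)
    calls = pd.DataFrame({
        "sample": samples["sample"].to_numpy()[si],
        "chrom": loci["chrom"].to_numpy()[li],
        "start": starts,
        "end": ends,
        "cn": cn,
        "num_snps": num_snps,
        "locus": loci["locus"].to_numpy()[li],
    })

    # junk calls that the call-level filters must remove
    n_junk = int(round(cfg.frac_bad_calls * n_calls))
    if n_junk:
        js = rng.integers(0, n_samples, n_junk)
        jc = rng.integers(0, cfg.n_chroms, n_junk)
        jstart = rng.integers(1, cfg.chrom_len_bp - 1000, n_junk)
        too_short = rng.random(n_junk) < 0.5
        jlen = np.where(too_short, rng.integers(100, 999, n_junk),
                        rng.integers(2000, 20_000, n_junk))
        jsnp = np.where(too_short, rng.integers(4, 8, n_junk),
                        rng.integers(1, 4, n_junk))
        junk = pd.DataFrame({
            "sample": samples["sample"].to_numpy()[js],
            "chrom": [f"chr{c + 1}" for c in jc],
            "start": jstart,
            "end": jstart + jlen - 1,
            "cn": rng.choice([0, 1, 3, 4], n_junk, p=[v for v in CN_CLASS_WEIGHTS.values()]),
            "num_snps": jsnp,
            "locus": "",
        })
        calls = pd.concat([calls, junk], ignore_index=True)
    calls = calls.sort_values(["chrom", "start", "sample"]).reset_index(drop=True)

    # QC metrics: most samples comfortably inside the gates
    qc = pd.DataFrame({
        "sample": samples["sample"],
        "lrr_sd": rng.uniform(0.05, 0.25, n_samples),
        "baf_drift": rng.uniform(0.0, 0.005, n_samples),
        "waviness": rng.uniform(0.0, 0.03, n_samples),
    })
    counts = calls["sample"].value_counts()
    qc["call_count"] = qc["sample"].map(counts).fillna(0).astype(int)
    n_bad = int(round(cfg.frac_bad_samples * n_samples))
    if n_bad:
        bad = rng.choice(n_samples, n_bad, replace=False)
        which = rng.integers(0, 3, n_bad)
        qc.loc[bad[which == 0], "lrr_sd"] = rng.uniform(0.3, 0.6, (which == 0).sum())
        qc.loc[bad[which == 1], "baf_drift"] = rng.uniform(0.01, 0.05, (which == 1).sum())
        qc.loc[bad[which == 2], "waviness"] = rng.uniform(0.05, 0.2, (which == 2).sum())

    probes = pd.DataFrame([
        (f"chr{c + 1}_p{k:05d}", f"chr{c + 1}", pos)
        for c in range(cfg.n_chroms)
        for k, pos in enumerate(range(cfg.probe_spacing_bp, cfg.chrom_len_bp + 1,
                                      cfg.probe_spacing_bp))
    ], columns=["probe", "chrom", "pos"])

    gene_len = rng.integers(5_000, 200_000, cfg.n_genes)
    gene_start = rng.integers(1, cfg.chrom_len_bp - 200_000, cfg.n_genes)
    genes = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in rng.integers(0, cfg.n_chroms, cfg.n_genes)],
        "start": gene_start,
        "end": gene_start + gene_len - 1,
        "name": [f"GENE{i:04d}" for i in range(cfg.n_genes)],
    }).sort_values(["chrom", "start"]).reset_index(drop=True)

    qtl_len = rng.integers(500_000, 8_000_000, cfg.n_qtls)
    qtl_start = rng.integers(1, max(cfg.chrom_len_bp - 8_000_000, 2), cfg.n_qtls)
    qtls = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in rng.integers(0, cfg.n_chroms, cfg.n_qtls)],
        "start": qtl_start,
        "end": qtl_start + qtl_len - 1,
        "name": [f"QTL{i:03d}" for i in range(cfg.n_qtls)],
        "ci_width_bp": qtl_len,
    }).sort_values(["chrom", "start"]).reset_index(drop=True)

    truth = loci.assign(
        is_planted=is_planted,
        target_variable=np.where(is_planted, cfg.target_variable, ""),
        effect=effects,
    )[["locus", "is_planted", "target_variable", "effect",
       "chrom", "start", "end", "polarity", "baseline_freq"]]

    return World(config=cfg, climate=climate, samples=samples, calls=calls,
                 sample_qc=qc, probes=probes, genes=genes, qtls=qtls, truth=truth)


def write_fixtures(world: World, out_dir) -> pd.DataFrame:
    """Write the world to ``out_dir`` as flat files; returns a path/row manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []

    def record(name, n):
        entries.append({"file": name, "rows": int(n)})

    record("calls.tsv", _io.write_calls_tsv(world.calls, out / "calls.tsv"))
    record("climate.tsv", _io.write_table(world.climate, out / "climate.tsv", index=True))
    record("samples.tsv", _io.write_table(world.samples, out / "samples.tsv"))
    record("sample_qc.tsv", _io.write_table(world.sample_qc, out / "sample_qc.tsv"))
    record("probes.tsv", _io.write_table(world.probes, out / "probes.tsv"))
    record("genes.gff3", _io.write_gff3(world.genes, out / "genes.gff3"))
    record("qtls.bed", _io.write_bed(world.qtls, out / "qtls.bed",
                                     extra_cols=("ci_width_bp",)))
    record("truth.tsv", _io.write_table(world.truth, out / "truth.tsv"))
    manifest = pd.DataFrame(entries)
    _io.write_table(manifest, out / "manifest.tsv")
    return manifest
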