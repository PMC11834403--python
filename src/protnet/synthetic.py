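"""Synthetic monthly amplicon time series with planted pairwise dependencies.

The generator emulates the sampling design of a multi-year coastal
time-series station: monthly sampling over roughly fifteen years with
weather-related gaps, annual-period seasonal cycles in many taxa, slow
interannual drift, and compositional count noise (sequencing reads are a
fixed-size multinomial draw, so absolute abundances are unobservable).

"Interactions" are planted as nonzero off-diagonal entries of a latent
Gaussian precision matrix: the residual log-abundances of interacting ASV
pairs are conditionally dependent given all other ASVs, which is exactly
the signal a graphical-lasso network is built to recover.  A toy
PIDA-style interaction database covering a known subset of the planted
edges allows the full annotation stage to be exercised against ground
truth.

All randomness derives from one master seed; each stage draws from its own
deterministic child stream, so every artifact is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import DBRecord, InteractionDB, write_interaction_db
from .containers import INTERACTION_TYPES, AsvTable, EnvTable, TaxonomyTable

DAYS_PER_YEAR = 365.25

# child-stream ids for the master seed (stable across releases)
_STREAMS = {
    "structure": 0, "latent": 1, "counts": 2, "months": 3,
    "env": 4, "db": 5, "taxonomy": 6,
}

_GENUS_POOL = [
    "Tripos", "Dinophysis", "Teleaulax", "Gymnodinium", "Heterocapsa",
    "Scrippsiella", "Chaetoceros", "Leptocylindrus", "Phaeocystis",
    "Chrysochromulina", "Eutintinnus", "Pelagodinium", "Micromonas",
    "Ostreococcus", "Cryothecomonas", "Pseudo-nitzschia", "Amphibelone",
    "Plagioselmis", "Kathablepharis", "Prorocentrum", "Strombidium",
    "Laboea", "Guinardia", "Thalassiosira", "Emiliania", "Pterosperma",
]

_SEASONAL_ENV_NAMES = [
    "temperature", "day_length", "salinity", "chl_fluorescence",
    "nitrate", "phosphate", "silicate", "oxygen",
]
_NOISE_ENV_NAMES = [
    "ssh", "mei", "beam_attenuation", "pp_rate", "ammonium",
    "sar11_fl", "sar11_pa", "flavo_fl", "flavo_pa", "synecho_fl",
    "sst_satellite", "chl_satellite",
]


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


@dataclass
class SyntheticConfig:
    """Study-design knobs for the generator.

    Defaults mirror the motivating sampling design: 177 monthly time points
    with roughly a third of months missed, annual cycles in half of the
    taxa, and a handful of strong planted dependencies.
    """

    n_asvs: int = 30
    n_months: int = 177
    missing_month_fraction: float = 0.31
    library_size: int = 100_000
    seasonal_fraction: float = 0.5
    seasonal_amplitude: float = 1.0
    drift_sd: float = 0.05
    n_planted_edges: int = 20
    partial_corr_strength: float = 0.4
    db_coverage: float = 0.5
    n_decoy_records: int = 10
    seed: int = 0
    start_date: str = "2003-09-01"
    baseline_sd: float = 1.0
    max_degree: int = 3

    def validate(self) -> None:
        if self.n_asvs <= 0 or self.n_months <= 0 or self.library_size <= 0:
            raise ValueError("n_asvs, n_months and library_size must be positive")
        max_edges = self.n_asvs * (self.n_asvs - 1) // 2
        if not 0 <= self.n_planted_edges <= max_edges:
            raise ValueError(f"n_planted_edges must be in [0, {max_edges}]")
        for name in ("missing_month_fraction", "seasonal_fraction", "db_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0 or (name == "missing_month_fraction" and v >= 1.0):
                raise ValueError(f"{name}={v} out of range")
        if not 0.0 < self.partial_corr_strength < 1.0:
            raise ValueError("partial_corr_strength must lie in (0, 1)")
        if self.seasonal_amplitude < 0 or self.drift_sd < 0:
            raise ValueError("seasonal_amplitude and drift_sd must be nonnegative")
        if self.n_decoy_records < 0:
            raise ValueError("n_decoy_records must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated community.

    ``planted_edges`` maps each unordered ASV-id pair to its interaction
    type; ``latent_precision`` has nonzero off-diagonal entries exactly at
    the planted edges.  The latent log-abundance matrix is kept so tests
    can verify structure (seasonality, partial correlations) without count
    noise.
    """

    planted_edges: dict[tuple[str, str], str]
    latent_precision: pd.DataFrame
    seasonal_ids: set[str]
    sample_dates: list
    sample_ids: list[str] = field(default_factory=list)
    latent: pd.DataFrame | None = None
    driver_map: dict[str, str] = field(default_factory=dict)

    def partial_correlation(self, a: str, b: str) -> float:
        th = self.latent_precision
        return -th.loc[a, b] / np.sqrt(th.loc[a, a] * th.loc[b, b])


def _planted_structure(config: SyntheticConfig):
    """Choose degree-capped random edges, interaction types and a
    unit-diagonal precision matrix that is positive definite."""
    rng = _rng(config.seed, "structure")
    p = config.n_asvs
    pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
    rng.shuffle(pairs)
    deg = np.zeros(p, dtype=int)
    edges = []
    for i, j in pairs:
        if len(edges) == config.n_planted_edges:
            break
        if deg[i] < config.max_degree and deg[j] < config.max_degree:
            edges.append((i, j))
            deg[i] += 1
            deg[j] += 1
    if len(edges) < config.n_planted_edges:
        raise ValueError("cannot place requested edges under the degree cap")

    types = list(INTERACTION_TYPES)
    edge_types = [types[k % 4] for k in range(len(edges))]
    rng.shuffle(edge_types)

    theta = np.eye(p)
    for (i, j), _ in zip(edges, edge_types):
        rho = config.partial_corr_strength
        if rng.random() < 0.3:
            rho = -rho
        # partial correlation -theta_ij/sqrt(theta_ii theta_jj) = rho
        theta[i, j] = theta[j, i] = -rho
    try:
        np.linalg.cholesky(theta)
    except np.linalg.LinAlgError:
        lo = np.linalg.eigvalsh(theta)[0]
        warnings.warn(
            f"constructed precision not positive definite (min eig {lo:.3f}); "
            "inflating diagonal and renormalizing — realized partial "
            "correlations will be weaker than requested"
        )
        theta += (abs(lo) + 0.05) * np.eye(p)
        d = 1.0 / np.sqrt(np.diag(theta))
        theta = theta * np.outer(d, d)
    return edges, edge_types, theta


def _make_taxonomy(config, edges, edge_types, asv_ids):
    """Assign eight-rank lineages so every database-matching rule is
    exercisable: Syndiniales parasites at group level, radiolarian and MAST
    symbionts at class/clade level, everything else genus-resolved."""
    rng = _rng(config.seed, "taxonomy")
    genus_pool = list(_GENUS_POOL) + [f"Genus{k:03d}" for k in range(200)]
    lineages: dict[str, list[str]] = {}
    synd_groups = ["I", "II", "III"]
    mast_clades = ["MAST-3E", "MAST-3F", "MAST-3I", "MAST-3L"]
    n_synd = n_mast = n_rad = 0

    def next_genus() -> str:
        return genus_pool.pop(0)

    def host_lineage(genus: str) -> list[str]:
        templates = [
            ["Eukaryota", "Alveolata", "Dinoflagellata", "Dinophyceae",
             "Dinophyceae", "Gymnodiniales", "Gymnodiniaceae", genus],
            ["Eukaryota", "Stramenopiles", "Ochrophyta", "Bacillariophyta",
             "Bacillariophyceae", "Chaetocerotales", "Chaetocerotaceae", genus],
            ["Eukaryota", "Haptista", "Haptophyta", "Prymnesiophyta",
             "Prymnesiophyceae", "Prymnesiales", "Prymnesiaceae", genus],
            ["Eukaryota", "Alveolata", "Ciliophora", "Spirotrichea",
             "Oligotrichia", "Tintinnida", "Tintinnidae", genus],
            ["Eukaryota", "Cryptista", "Cryptophyta", "Cryptophyceae",
             "Cryptomonadales", "Pyrenomonadales", "Geminigeraceae", genus],
        ]
        return list(templates[rng.integers(len(templates))])

    def assign(asv, lineage):
        if asv not in lineages:
            lineages[asv] = lineage

    for (i, j), etype in zip(edges, edge_types):
        a, b = asv_ids[i], asv_ids[j]
        if etype == "parasitism":
            g = synd_groups[n_synd % 3]
            n_synd += 1
            assign(a, ["Eukaryota", "Alveolata", "Dinoflagellata", "Syndiniales",
                       f"Syndiniales-Group-{g}", f"Syndiniales-Group-{g}-Clade-1",
                       "Syndiniales-fam", ""])
            assign(b, host_lineage(next_genus()))
        elif etype == "symbiosis" and n_rad <= n_mast:
            n_rad += 1
            cls = ("Acantharea" if n_rad % 2 else "Polycystinea")
            order = "Acantharea-Clade-F" if cls == "Acantharea" else "Nassellaria"
            assign(a, ["Eukaryota", "Rhizaria", "Radiolaria", "Radiolaria_X",
                       cls, order, f"{cls}-fam", ""])
            assign(b, host_lineage(next_genus()))
        elif etype == "symbiosis":
            clade = mast_clades[n_mast % len(mast_clades)]
            n_mast += 1
            assign(a, ["Eukaryota", "Stramenopiles", "Bigyra", "Opalozoa",
                       "MAST-3", clade, f"{clade}-fam", ""])
            assign(b, host_lineage(next_genus()))
        else:  # predation / unresolved: plain genus-genus
            assign(a, host_lineage(next_genus()))
            assign(b, host_lineage(next_genus()))

    for asv in asv_ids:
        if asv not in lineages:
            lineages[asv] = host_lineage(next_genus())
    return TaxonomyTable({asv: lineages[asv] for asv in asv_ids})


def generate_community(
    config: SyntheticConfig, depth: str = "surface"
) -> tuple[AsvTable, TaxonomyTable, SyntheticTruth]:
    """Generate one depth's ASV count table, taxonomy, and ground truth.

    Latent per-ASV log abundance = baseline + annual sinusoid (seasonal
    ASVs only) + random-walk drift + multivariate Gaussian residual with
    covariance equal to the inverse of the planted precision matrix.
    Counts are a multinomial draw of ``library_size`` reads over the
    softmax of each month's latent vector; a fraction of months is then
    dropped to emulate missed cruises.
    """
    config.validate()
    p, n = config.n_asvs, config.n_months
    asv_ids = [f"ASV{k:04d}" for k in range(p)]

    edges, edge_types, theta = _planted_structure(config)
    taxonomy = _make_taxonomy(config, edges, edge_types, asv_ids)

    rng = _rng(config.seed, "latent")
    all_dates = pd.date_range(config.start_date, periods=n, freq="MS")
    t_days = (all_dates - all_dates[0]).days.to_numpy(float)

    baseline = rng.normal(0.0, config.baseline_sd, size=p)
    n_seasonal = int(round(config.seasonal_fraction * p))
    seasonal_idx = rng.choice(p, size=n_seasonal, replace=False)
    phases = rng.uniform(0, 2 * np.pi, size=p)
    seasonal = np.zeros((n, p))
    seasonal[:, seasonal_idx] = config.seasonal_amplitude * np.sin(
        2 * np.pi * t_days[:, None] / DAYS_PER_YEAR + phases[None, seasonal_idx]
    )
    drift = np.cumsum(rng.normal(0.0, config.drift_sd, size=(n, p)), axis=0)
    sigma = np.linalg.inv(theta)
    chol = np.linalg.cholesky(sigma)
    resid = rng.standard_normal((n, p)) @ chol.T
    latent = baseline[None, :] + seasonal + drift + resid

    crng = _rng(config.seed, "counts")
    probs = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [crng.multinomial(config.library_size, probs[t]) for t in range(n)]
    )

    mrng = _rng(config.seed, "months")
    n_drop = int(round(config.missing_month_fraction * n))
    dropped = set(mrng.choice(n, size=n_drop, replace=False).tolist())
    keep = np.array([t for t in range(n) if t not in dropped])

    sample_ids = [f"SPOT_{depth}_{d:%Y_%m}" for d in all_dates[keep]]
    table = AsvTable(
        counts=pd.DataFrame(counts[keep], index=sample_ids, columns=asv_ids),
        dates=pd.Series(all_dates[keep], index=sample_ids),
        depth=pd.Series(depth, index=sample_ids),
    )
    truth = SyntheticTruth(
        planted_edges={
            tuple(sorted((asv_ids[i], asv_ids[j]))): etype
            for (i, j), etype in zip(edges, edge_types)
        },
        latent_precision=pd.DataFrame(theta, index=asv_ids, columns=asv_ids),
        seasonal_ids={asv_ids[k] for k in seasonal_idx},
        sample_dates=list(all_dates[keep]),
        sample_ids=sample_ids,
        latent=pd.DataFrame(latent[keep], index=sample_ids, columns=asv_ids),
    )
    return table, taxonomy, truth


def generate_env(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    n_seasonal: int = 8,
    n_noise: int = 12,
    n_driver: int = 4,
    missing_fraction: float = 0.1,
    driver_noise_sd: float = 0.2,
    noise_sd: float = 0.3,
) -> EnvTable:
    """Environmental/biological covariate table on the retained samples.

    Seasonal variables are annual sinusoids plus noise, noise variables are
    white, and driver variables are linear functions of designated ASVs'
    latent abundances plus noise (their column names record the source ASV,
    also kept in ``truth.driver_map``).  A fraction of cells is masked
    missing, to be filled by the imputation stage.
    """
    if not truth.sample_dates:
        raise ValueError("truth has no sample dates")
    if not 0.0 <= missing_fraction < 1.0:
        raise ValueError("missing_fraction out of range")
    rng = _rng(config.seed, "env")
    dates = pd.DatetimeIndex(truth.sample_dates)
    t_days = (dates - dates[0]).days.to_numpy(float)
    m = len(dates)

    cols, names = [], []
    for k in range(n_seasonal):
        phase = rng.uniform(0, 2 * np.pi)
        cols.append(np.sin(2 * np.pi * t_days / DAYS_PER_YEAR + phase)
                    + rng.normal(0, noise_sd, m))
        names.append(_SEASONAL_ENV_NAMES[k] if k < len(_SEASONAL_ENV_NAMES)
                     else f"seasonal_{k}")
    for k in range(n_noise):
        cols.append(rng.normal(0, 1, m))
        names.append(_NOISE_ENV_NAMES[k] if k < len(_NOISE_ENV_NAMES)
                     else f"noise_{k}")
    driver_map = {}
    if n_driver > 0:
        if truth.latent is None:
            raise ValueError("driver variables need truth.latent")
        asvs = rng.choice(truth.latent.columns, size=n_driver, replace=False)
        for asv in asvs:
            name = f"driver_{asv}"
            cols.append(truth.latent[asv].to_numpy()
                        + rng.normal(0, driver_noise_sd, m))
            names.append(name)
            driver_map[name] = asv
    truth.driver_map = driver_map

    values = np.column_stack(cols)
    mask = rng.random(values.shape) < missing_fraction
    values[mask] = np.nan
    return EnvTable(pd.DataFrame(values, index=truth.sample_ids, columns=names))


def generate_interaction_db(
    truth: SyntheticTruth,
    taxonomy: TaxonomyTable,
    config: SyntheticConfig,
) -> InteractionDB:
    """Toy interaction database covering ``db_coverage`` of the planted
    edges, plus decoy records about taxa absent from the community.

    Each covered edge is recorded at the matching granularity its taxa
    require: the first available key per endpoint, special ranks (group /
    host class / clade) before genus.  Edges whose taxonomy lacks any
    usable rank are skipped with a warning.
    """
    rng = _rng(config.seed, "db")
    edges = sorted(truth.planted_edges)
    n_cover = int(round(config.db_coverage * len(edges)))
    chosen_idx = sorted(rng.choice(len(edges), size=n_cover, replace=False).tolist())
    records = []
    for k in chosen_idx:
        a, b = edges[k]
        keys_a = taxonomy.match_keys(a)
        keys_b = taxonomy.match_keys(b)
        # every matching rule pairs a genus with a genus or one special
        # rank, so the record needs genus resolution on at least one side
        pick = None
        for ka_rank, ka in keys_a:
            for kb_rank, kb in keys_b:
                if "genus" in (ka_rank, kb_rank):
                    pick = ((ka_rank, ka), (kb_rank, kb))
                    break
            if pick:
                break
        if pick is None:
            warnings.warn(f"edge {(a, b)} has no database-expressible rank "
                          "combination; skipped")
            continue
        (ra, ka), (rb, kb) = pick
        records.append(DBRecord(
            record_id=f"REC{len(records):04d}",
            taxon_a_key=ka, taxon_a_rank=ra,
            taxon_b_key=kb, taxon_b_rank=rb,
            interaction_type=truth.planted_edges[(a, b)],
        ))
    types = list(INTERACTION_TYPES)
    for k in range(config.n_decoy_records):
        records.append(DBRecord(
            record_id=f"DEC{k:04d}",
            taxon_a_key=f"Decoyella{2 * k}", taxon_a_rank="genus",
            taxon_b_key=f"Decoyella{2 * k + 1}", taxon_b_rank="genus",
            interaction_type=types[int(rng.integers(4))],
        ))
    return InteractionDB(records, provenance=f"synthetic(seed={config.seed})")


def write_dataset(
    outdir,
    table: AsvTable,
    taxonomy: TaxonomyTable,
    env: EnvTable | None = None,
    db: InteractionDB | None = None,
    truth: SyntheticTruth | None = None,
) -> None:
    """Write the standard TSV layout: counts, metadata, taxonomy, env,
    interaction DB, and a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = table.counts.copy()
    counts.index.name = "sample_id"
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    meta = pd.DataFrame({
        "sample_id": table.sample_ids,
        "date": [f"{d:%Y-%m-%d}" for d in table.dates],
        "depth": table.depth.to_numpy(),
    })
    meta.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    tax = pd.DataFrame({
        "asv_id": taxonomy.asv_ids,
        "lineage": [taxonomy.lineage_string(a) for a in taxonomy.asv_ids],
    })
    tax.to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    if env is not None:
        ev = env.values.copy()
        ev.index.name = "sample_id"
        ev.to_csv(outdir / "env.tsv", sep="\t")
    if db is not None:
        write_interaction_db(db, outdir / "interactions.tsv")
    if truth is not None:
        payload = {
            "planted_edges": [
                {"asv_a": a, "asv_b": b, "interaction_type": t}
                for (a, b), t in sorted(truth.planted_edges.items())
            ],
            "seasonal_ids": sorted(truth.seasonal_ids),
            "sample_ids": truth.sample_ids,
            "driver_map": truth.driver_map,
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
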