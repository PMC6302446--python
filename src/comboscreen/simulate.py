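"""Seeded synthetic combination screens with known ground truth.

The generator emulates the shapes and statistics of a pairwise drug screen
against a tumor cell-line panel so the whole pipeline is testable without
any external download:

* latent cell factors project linearly to each omics assay (expression and
  microRNA emitted in already-log-transformed units, protein abundance in
  raw units so the log(x+1) step is exercised);
* latent drug factors project to a descriptor matrix; a configured fraction
  of descriptor columns is masked >= 90% missing to exercise the sparse-
  column filter, plus light scattered missingness for the imputer;
* single-agent growth follows a monotone decreasing dose curve of a latent
  cell-drug potency; pair growth at each dose combination is the truncated-
  product expectation of the single growths plus a planted synergy offset
  for labeled pairs plus noise.  Raw growth can drift slightly above 1
  (exercising the cap) and the marginal is skewed toward nonresponse.

Planted synergy is a deterministic function of the drug latent factors (the
top ``synergy_frac`` quantile of a symmetric latent interaction score), so
it is in principle learnable from descriptors; the offset scales with the
dose product, so the minimum-growth dose carries the full strength.  All
randomness flows from one root seed via named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import MatrixPreprocessor
from .screen import aggregate_min_growth, filter_records, validate_screen
from .scoring import expected_growth


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Study conditions of the synthetic screen.

    Defaults give a small panel (20 cell lines x 15 drugs, 105 unordered
    pairs) with weak measurement noise and 10% of pairs planted as strongly
    synergistic (BestComboScore near -50 points, the strong-enhancer range).
    """

    n_cells: int = 20
    n_drugs: int = 15
    latent_dim: int = 5
    omics_dims: dict = field(
        default_factory=lambda: {"expression": 50, "microrna": 20, "proteome": 30}
    )
    descriptor_dim: int = 40
    missing_col_frac: float = 0.15
    scatter_missing_frac: float = 0.02
    assay_noise_sd: float = 0.05
    descriptor_noise_sd: float = 0.05
    noise_sd: float = 0.02
    synergy_frac: float = 0.1
    synergy_strength: float = -0.5
    qc_fail_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.synergy_frac <= 1:
            raise ValueError("synergy_frac must be in [0, 1]")
        if self.synergy_strength > 0:
            raise ValueError("synergy_strength must be <= 0 (growth offset)")


@dataclass
class Entities:
    """Generated feature matrices plus the latent ground truth behind them."""

    cell_features: dict  # name -> DataFrame (raw, as a reader would see them)
    drug_features: pd.DataFrame
    cell_latents: np.ndarray
    drug_latents: np.ndarray
    cell_ids: list
    drug_ids: list
    drug_n_doses: np.ndarray  # 3 or 5 single-agent concentrations per drug


@dataclass
class SyntheticScreen:
    """Dosed records plus the noise-free designed truth."""

    records: pd.DataFrame
    truth_response: pd.DataFrame  # designed min growth per tuple, noise-free
    synergy_labels: set  # unordered pair keys planted as synergistic
    entities: Entities


def generate_entities(cfg: SimConfig) -> Entities:
    """Generate cell omics matrices and the drug descriptor matrix."""
    for name, dim in cfg.omics_dims.items():
        if dim < cfg.latent_dim:
            raise ValueError(f"assay {name!r} width {dim} < latent_dim {cfg.latent_dim}")
    if cfg.descriptor_dim < cfg.latent_dim:
        raise ValueError("descriptor width < latent_dim")

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(3)[0])

    cell_ids = [f"CL{i:02d}" for i in range(1, cfg.n_cells + 1)]
    drug_ids = [f"DR{i:02d}" for i in range(1, cfg.n_drugs + 1)]
    U = rng.normal(size=(cfg.n_cells, cfg.latent_dim))
    V = rng.normal(size=(cfg.n_drugs, cfg.latent_dim))

    cell_features = {}
    for name, dim in cfg.omics_dims.items():
        W = rng.normal(size=(cfg.latent_dim, dim)) / np.sqrt(cfg.latent_dim)
        M = U @ W + rng.normal(scale=cfg.assay_noise_sd, size=(cfg.n_cells, dim))
        if name == "proteome":
            # raw abundance units: positive, log(x+1) recovers the latent signal
            M = np.expm1(np.clip(M + 3.0, 0.0, None))
        cell_features[name] = pd.DataFrame(
            M, index=cell_ids, columns=[f"{name}_{j}" for j in range(dim)]
        )

    P = rng.normal(size=(cfg.latent_dim, cfg.descriptor_dim)) / np.sqrt(cfg.latent_dim)
    D = V @ P + rng.normal(scale=cfg.descriptor_noise_sd, size=(cfg.n_drugs, cfg.descriptor_dim))
    drugs = pd.DataFrame(D, index=drug_ids, columns=[f"desc_{j}" for j in range(cfg.descriptor_dim)])

    n_masked = int(round(cfg.missing_col_frac * cfg.descriptor_dim))
    if n_masked:
        masked_cols = rng.choice(cfg.descriptor_dim, size=n_masked, replace=False)
        for c in masked_cols:
            # >= 90% of drug rows missing: the sparse-column filter must drop these
            n_missing = max(int(np.ceil(0.9 * cfg.n_drugs)), cfg.n_drugs - 1)
            rows = rng.choice(cfg.n_drugs, size=n_missing, replace=False)
            drugs.iloc[rows, c] = np.nan
    if cfg.scatter_missing_frac:
        keep = drugs.notna().to_numpy()
        scatter = rng.uniform(size=drugs.shape) < cfg.scatter_missing_frac
        drugs = drugs.mask(pd.DataFrame(scatter & keep, index=drugs.index, columns=drugs.columns))

    n_doses = rng.choice([3, 5], size=cfg.n_drugs)
    return Entities(
        cell_features=cell_features,
        drug_features=drugs,
        cell_latents=U,
        drug_latents=V,
        cell_ids=cell_ids,
        drug_ids=drug_ids,
        drug_n_doses=n_doses,
    )


def _max_effect(U, V):
    """Latent full-dose effect in (0, 2): growth at top dose is 1 - effect."""
    x = (U @ V.T) / np.sqrt(U.shape[1])
    return 2.0 * _sigmoid(1.5 * x - 1.0)


def planted_pairs(cfg: SimConfig, entities: Entities) -> set:
    """Unordered pair keys in the top synergy_frac of latent interaction."""
    V = entities.drug_latents
    n = cfg.n_drugs
    ii, jj = np.triu_indices(n, k=1)
    q = (V[ii] * V[jj]).sum(axis=1) / np.sqrt(cfg.latent_dim)
    n_plant = int(np.floor(cfg.synergy_frac * len(ii)))
    order = np.argsort(-q, kind="stable")[:n_plant]
    ids = entities.drug_ids
    return {tuple(sorted((ids[ii[k]], ids[jj[k]]))) for k in order}


def generate_screen(cfg: SimConfig, entities: Entities) -> SyntheticScreen:
    """Generate dosed records and the designed noise-free response truth."""
    ss = np.random.SeedSequence(cfg.seed).spawn(3)
    rng_screen = np.random.default_rng(ss[1])
    rng_noise = np.random.default_rng(ss[2])

    U, V = entities.cell_latents, entities.drug_latents
    cells, drugs = entities.cell_ids, entities.drug_ids
    effect = _max_effect(U, V)  # n_cells x n_drugs
    labels = planted_pairs(cfg, entities)

    rows = []
    truth = []
    # single agents: monotone decreasing dose curve, 3 or 5 concentrations
    for ci, cell in enumerate(cells):
        for di, drug in enumerate(drugs):
            T = int(entities.drug_n_doses[di])
            for t in range(1, T + 1):
                g = 1.0 - effect[ci, di] * t / T
                g += rng_noise.normal(scale=cfg.noise_sd)
                rows.append((cell, drug, None, t - 1, None, max(g, -1.0), True))
            truth.append((cell, drug, None, max(1.0 - effect[ci, di], -1.0)))

    # pairs: ordered (a, b) with a before b in panel order; grid T_a x 3
    pair_idx = [(i, j) for i in range(cfg.n_drugs) for j in range(i + 1, cfg.n_drugs)]
    for ci, cell in enumerate(cells):
        for di, dj in pair_idx:
            a, b = drugs[di], drugs[dj]
            s = cfg.synergy_strength if tuple(sorted((a, b))) in labels else 0.0
            Ta = int(entities.drug_n_doses[di])
            for ta in range(1, Ta + 1):
                for tb in range(1, 4):
                    ga = 1.0 - effect[ci, di] * ta / Ta
                    gb = 1.0 - effect[ci, dj] * tb / 3.0
                    z = expected_growth(max(ga, -1.0), max(gb, -1.0))
                    g = z + s * (ta / Ta) * (tb / 3.0)
                    g += rng_noise.normal(scale=cfg.noise_sd)
                    rows.append((cell, a, b, ta - 1, tb - 1, max(g, -1.0), True))
            ga = max(1.0 - effect[ci, di], -1.0)
            gb = max(1.0 - effect[ci, dj], -1.0)
            truth.append((cell, a, b, max(expected_growth(ga, gb) + s, -1.0)))

    records = pd.DataFrame(rows, columns=["CELL", "DRUG_A", "DRUG_B", "DOSE_A", "DOSE_B", "GROWTH", "QC"])
    if cfg.qc_fail_frac:
        fail = rng_screen.uniform(size=len(records)) < cfg.qc_fail_frac
        records.loc[fail, "QC"] = False
        # QC failures carry corrupted measurements, so filtering matters
        noise = rng_screen.normal(scale=0.5, size=int(fail.sum()))
        records.loc[fail, "GROWTH"] = np.clip(
            records.loc[fail, "GROWTH"].to_numpy() + noise, -1.0, 1.3
        )
    records = validate_screen(records)
    truth_df = pd.DataFrame(truth, columns=["CELL", "DRUG_A", "DRUG_B", "MIN_GROWTH"])
    truth_df["DRUG_B"] = truth_df["DRUG_B"].astype("string")
    return SyntheticScreen(
        records=records, truth_response=truth_df, synergy_labels=labels, entities=entities
    )


def generate(cfg: SimConfig | None = None) -> SyntheticScreen:
    """Entities + screen in one call."""
    cfg = cfg or SimConfig()
    return generate_screen(cfg, generate_entities(cfg))


def prepare_features(entities: Entities):
    """Run the canonical preprocessing on generated matrices.

    Expression and microRNA arrive log-transformed; protein abundance is raw
    and gets log(x+1); descriptors are not transformed but are filtered for
    sparse columns.  All matrices end imputed and min-max scaled to [0, 1].
    Returns ``(cell_features: dict of DataFrame, drug_features: DataFrame)``.
    """
    cell_out = {}
    for name, mat in entities.cell_features.items():
        prep = MatrixPreprocessor(log1p=(name == "proteome"), missing_frac=None)
        cell_out[name] = prep.fit(mat).transform(mat)
    dprep = MatrixPreprocessor(log1p=False, missing_frac=0.9)
    drug_out = dprep.fit(entities.drug_features).transform(entities.drug_features)
    return cell_out, drug_out


def simulate_dataset(cfg: SimConfig | None = None):
    """Full path from generator to a model-ready design matrix.

    Generates a screen, drops QC failures, aggregates minimum growth,
    preprocesses the feature matrices, and assembles the design matrix.
    Returns ``(dataset, screen)`` where ``screen`` carries the ground truth.
    """
    from .dataset import build_dataset

    screen = generate(cfg)
    passed = filter_records(screen.records, require_qc=True)
    responses = aggregate_min_growth(passed)
    cell_features, drug_features = prepare_features(screen.entities)
    dataset = build_dataset(responses, cell_features, drug_features)
    return dataset, screen
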