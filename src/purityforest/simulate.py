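"""Synthetic tumor-stroma admixture cohorts with known purity.

The generator emulates the structure a methylation-based purity estimator
is trained on: each entity has its own tumor methylome, all samples share a
stromal/immune methylome, and a bulk sample with purity p measures the
convex combination p*tumor + (1-p)*stroma per CpG, perturbed by noise on
the logit scale (which preserves [0,1] and mimics the heteroscedastic error
of beta values).  A planted subset of "informative" probes has, in every
entity, a tumor reference at least 0.4 away from a mid-methylated stromal
reference, with the side (hyper- vs hypomethylated) varying across entities:
across the cohort these probes are genuinely multimodal -- the two-cluster
signal the dip screen detects -- while within an entity the beta value moves
linearly with purity.  (A single shared tumor/stroma pair per probe would
not do: purity is unimodal and the dip is affine invariant, so pure
admixture spread is invisible to a multimodality screen; in real pan-cancer
cohorts the bimodality likewise comes from entity-wise differences in tumor
methylomes.)  A separate small panel of immune-hypomethylated probes (tumor
methylated in every entity) emulates the LUMP signature.  Two gold-standard
label sets are emulated: an ABSOLUTE-like set (truth plus logit noise) and
an ESTIMATE-like set with an additional positive logit offset, reproducing
the systematic ESTIMATE > ABSOLUTE ordering seen in practice.

Defaults define the reference study conditions: 3 entities x 100 samples,
20,000 probes with 600 informative, purity ~ Beta(8, 2) per entity
(mean 0.8, the high-purity regime typical of resected tumors), logit noise
sd 0.3, label offset +0.25 logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BetaMatrix,
    ProbeAnnotation,
    PurityTable,
    ValidationError,
    write_beta_matrix,
    write_probe_annotation,
    write_purity_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "draw_reference_profiles",
    "simulate_cohort",
    "synthetic_annotation",
    "make_fixture_suite",
]

_EPS = 1e-6


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stage]))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic cohort (all rates/SDs on the scales
    named in the field comments)."""

    n_entities: int = 3
    samples_per_entity: int = 100
    n_probes: int = 20_000
    n_informative: int = 600
    purity_alpha: float = 8.0  # Beta-law shape parameters of true purity
    purity_beta: float = 2.0
    noise_sd: float = 0.3  # logit-scale measurement noise on betas
    label_offset_estimate: float = 0.25  # mean logit shift of ESTIMATE-like labels
    label_noise_sd: float = 0.15  # logit-scale noise of both label sets
    missing_rate: float = 0.0  # fraction of beta cells masked NA
    n_entity_probes: int = 500  # probes carrying entity-specific tumor shifts
    entity_shift_sd: float = 0.8  # logit sd of those shifts
    lump_panel_size: int = 44  # immune-hypomethylated marker probes
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_probes:
            raise ValidationError("n_informative cannot exceed n_probes")
        if self.n_informative + self.n_entity_probes + self.lump_panel_size > self.n_probes:
            raise ValidationError("informative + entity + panel probes exceed n_probes")
        for name in ("n_entities", "samples_per_entity", "n_probes"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_informative < 0:
            raise ValidationError("n_informative must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        for name in ("noise_sd", "label_noise_sd", "entity_shift_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class SyntheticCohort:
    """A simulated cohort: betas, ground truth and emulated gold standards."""

    betas: BetaMatrix
    truth: PurityTable  # source SYNTHETIC_TRUTH
    labels_absolute_like: PurityTable  # source ABSOLUTE
    labels_estimate_like: PurityTable  # source ESTIMATE
    entity: pd.Series  # sample -> entity label
    informative_probes: tuple
    entity_probes: tuple
    lump_panel: tuple
    config: SimulationConfig


def draw_reference_profiles(cfg: SimulationConfig):
    """Per-entity tumor methylomes and the shared stromal methylome.

    Informative probes: stroma mid-methylated (U(0.42, 0.58), the average of
    a mixed stromal cell population), tumor reference per entity on an
    extreme side at least 0.4 away from stroma, with the side vector
    non-constant across entities (when there are >= 2 entities) so the probe
    is genuinely multimodal across the cohort.  The LUMP panel probes have a
    hypomethylated stroma (U(0.05, 0.15)) and a methylated tumor reference
    in every entity (U(0.75, 0.95)).  All other probes share one baseline
    value between tumor and stroma, except the entity-specific subset whose
    tumor reference is shifted per entity on the logit scale.

    Returns ``(tumor, stroma, informative_probes, entity_probes, lump_panel)``
    with ``tumor`` a probes x entities DataFrame and ``stroma`` a Series.
    """
    rng = _rng(cfg.seed, 1)
    probes = pd.Index([f"cg{i:08d}" for i in range(cfg.n_probes)], name="probe_id")
    entities = [f"entity{e + 1}" for e in range(cfg.n_entities)]

    order = rng.permutation(cfg.n_probes)
    informative = probes[np.sort(order[: cfg.n_informative])]
    stop = cfg.n_informative + cfg.n_entity_probes
    entity_specific = probes[np.sort(order[cfg.n_informative : stop])]
    lump_panel = probes[np.sort(order[stop : stop + cfg.lump_panel_size])]

    # baseline methylome: most probes near 0 or 1, as on real arrays
    baseline = np.clip(rng.beta(0.5, 0.5, size=cfg.n_probes), 0.02, 0.98)
    stroma = pd.Series(baseline.copy(), index=probes, name="stroma")
    tumor = pd.DataFrame(
        np.tile(baseline[:, None], (1, cfg.n_entities)), index=probes, columns=entities
    )

    if cfg.n_informative:
        s_ref = rng.uniform(0.42, 0.58, size=cfg.n_informative)
        stroma.loc[informative] = s_ref
        sides = rng.integers(0, 2, size=(cfg.n_informative, cfg.n_entities))
        if cfg.n_entities >= 2:  # redraw constant side vectors
            while True:
                const = sides.min(axis=1) == sides.max(axis=1)
                if not const.any():
                    break
                sides[const] = rng.integers(0, 2, size=(int(const.sum()), cfg.n_entities))
        u = rng.random(size=(cfg.n_informative, cfg.n_entities))
        lo_ref = 0.01 + u * (s_ref[:, None] - 0.4 - 0.01)  # in [0.01, s - 0.4]
        hi_ref = (s_ref[:, None] + 0.4) + u * (0.99 - s_ref[:, None] - 0.4)
        tumor.loc[informative, :] = np.where(sides == 1, hi_ref, lo_ref)

    if cfg.lump_panel_size:
        stroma.loc[lump_panel] = rng.uniform(0.05, 0.15, size=cfg.lump_panel_size)
        tumor.loc[lump_panel, :] = rng.uniform(
            0.75, 0.95, size=(cfg.lump_panel_size, cfg.n_entities)
        )

    if cfg.n_entity_probes:
        shifts = rng.normal(0.0, cfg.entity_shift_sd, size=(cfg.n_entity_probes, cfg.n_entities))
        base = tumor.loc[entity_specific, :].to_numpy()
        tumor.loc[entity_specific, :] = _logistic(_logit(base) + shifts)

    return tumor, stroma, tuple(informative), tuple(entity_specific), tuple(lump_panel)


def simulate_cohort(cfg: SimulationConfig = SimulationConfig()) -> SyntheticCohort:
    """Draw a full cohort under the configured study conditions.

    Per sample j of entity e with purity p_j ~ Beta(alpha, beta):
    ``beta_ij = logistic(logit(p_j * t_ie + (1 - p_j) * s_i) + eps_ij)`` with
    eps ~ N(0, noise_sd) (skipped entirely when noise_sd is 0, so noise-free
    betas are the exact convex combination); labels are truth plus logit
    noise, the ESTIMATE-like set with the positive offset added first.
    """
    tumor, stroma, informative, entity_specific, lump_panel = draw_reference_profiles(cfg)
    entities = list(tumor.columns)
    n_samples = cfg.n_entities * cfg.samples_per_entity
    sample_ids = []
    sample_entity = []
    for e, ent in enumerate(entities):
        for j in range(cfg.samples_per_entity):
            sample_ids.append(f"{ent}_s{j + 1:03d}")
            sample_entity.append(ent)
    entity = pd.Series(sample_entity, index=pd.Index(sample_ids, name="sample_id"), name="group")

    rng_p = _rng(cfg.seed, 2)
    purity = rng_p.beta(cfg.purity_alpha, cfg.purity_beta, size=n_samples)
    truth = PurityTable(
        purity=pd.Series(purity, index=entity.index, name="purity"),
        source="SYNTHETIC_TRUTH",
        group=entity.copy(),
    )

    t_cols = tumor.loc[:, sample_entity].to_numpy()  # probes x samples
    s_col = stroma.to_numpy()[:, None]
    mix = purity[None, :] * t_cols + (1.0 - purity[None, :]) * s_col

    if cfg.lump_panel_size:
        # at the immune-marker probes the stromal compartment is itself a
        # mixture: an immune fraction (hypomethylated, the stroma reference)
        # and a methylated non-immune remainder -- this is what keeps a
        # LUMP-style score an imperfect proxy of purity, as in real cohorts
        rng_imm = _rng(cfg.seed, 7)
        immune_frac = rng_imm.uniform(0.4, 1.0, size=n_samples)
        nonimmune_ref = rng_imm.uniform(0.6, 0.9, size=cfg.lump_panel_size)
        rows = tumor.index.get_indexer(list(lump_panel))
        s_eff = (
            immune_frac[None, :] * s_col[rows]
            + (1.0 - immune_frac[None, :]) * nonimmune_ref[:, None]
        )
        mix[rows] = purity[None, :] * t_cols[rows] + (1.0 - purity[None, :]) * s_eff
    if cfg.noise_sd > 0:
        rng_n = _rng(cfg.seed, 3)
        noise = rng_n.normal(0.0, cfg.noise_sd, size=mix.shape)
        betas = np.clip(_logistic(_logit(mix) + noise), 0.0, 1.0)
    else:
        betas = np.clip(mix, 0.0, 1.0)

    if cfg.missing_rate > 0:
        rng_m = _rng(cfg.seed, 5)
        mask = rng_m.random(betas.shape) < cfg.missing_rate
        betas = np.where(mask, np.nan, betas)

    beta_matrix = BetaMatrix(
        pd.DataFrame(betas, index=tumor.index, columns=entity.index)
    )

    rng_l = _rng(cfg.seed, 4)
    base_logit = _logit(purity)
    eta_abs = rng_l.normal(0.0, cfg.label_noise_sd, size=n_samples)
    eta_est = rng_l.normal(0.0, cfg.label_noise_sd, size=n_samples)
    labels_abs = np.clip(_logistic(base_logit + eta_abs), 0.0, 1.0)
    labels_est = np.clip(_logistic(base_logit + cfg.label_offset_estimate + eta_est), 0.0, 1.0)

    return SyntheticCohort(
        betas=beta_matrix,
        truth=truth,
        labels_absolute_like=PurityTable(
            purity=pd.Series(labels_abs, index=entity.index, name="purity"),
            source="ABSOLUTE",
            group=entity.copy(),
        ),
        labels_estimate_like=PurityTable(
            purity=pd.Series(labels_est, index=entity.index, name="purity"),
            source="ESTIMATE",
            group=entity.copy(),
        ),
        entity=entity,
        informative_probes=informative,
        entity_probes=entity_specific,
        lump_panel=lump_panel,
        config=cfg,
    )


_ISLAND_POOL = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
_ISLAND_WEIGHTS = (0.31, 0.13, 0.10, 0.05, 0.05, 0.36)
_REGION_POOL = ("TSS200", "TSS1500", "5'UTR", "1stExon", "Body", "3'UTR")


def synthetic_annotation(probe_ids, seed: int = 0, n_genes: int = 400, n_tsg: int = 40):
    """Toy manifest-style annotation plus a matching tumor-suppressor list.

    Gene symbols, region relations and island categories are drawn with
    roughly array-like frequencies; symbols are synthetic (``GENE####`` /
    ``TSG###``).  Returns ``(ProbeAnnotation, tsg_symbols)``.
    """
    rng = _rng(seed, 6)
    probe_ids = list(probe_ids)
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    tsg = [f"TSG{i:03d}" for i in range(n_tsg)]
    pool = genes + tsg
    records = {"gene_symbols": [], "gene_region": [], "island_relation": []}
    for _ in probe_ids:
        n_sym = rng.choice([0, 1, 2], p=[0.35, 0.55, 0.10])
        symbols = frozenset(rng.choice(pool, size=n_sym, replace=False)) if n_sym else frozenset()
        if symbols:
            k = int(rng.choice([1, 2], p=[0.85, 0.15]))
            regions = frozenset(rng.choice(_REGION_POOL, size=k, replace=False))
        else:
            regions = frozenset()
        records["gene_symbols"].append(symbols)
        records["gene_region"].append(regions)
        records["island_relation"].append(str(rng.choice(_ISLAND_POOL, p=_ISLAND_WEIGHTS)))
    table = pd.DataFrame(records, index=pd.Index(probe_ids, name="probe_id"))
    return ProbeAnnotation(table), tuple(tsg)


def make_fixture_suite(out_dir, cfg: SimulationConfig = SimulationConfig()) -> dict:
    """Write a deterministic cohort plus toy annotation, TSG list and a
    placeholder LUMP panel (synthetic probe ids) to ``out_dir``.

    The panel file lists the generator's immune-hypomethylated marker
    probes, mirroring the immune-hypomethylation logic of LUMP.  Repeated
    calls with the same config are byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg)
    panel = cohort.lump_panel

    ann, tsg = synthetic_annotation(cohort.betas.probe_ids, seed=cfg.seed)
    paths = {
        "betas": write_beta_matrix(cohort.betas, out_dir / "betas.tsv"),
        "truth": write_purity_table(cohort.truth, out_dir / "purity_truth.tsv"),
        "labels_absolute": write_purity_table(
            cohort.labels_absolute_like, out_dir / "purity_absolute_like.tsv"
        ),
        "labels_estimate": write_purity_table(
            cohort.labels_estimate_like, out_dir / "purity_estimate_like.tsv"
        ),
        "annotation": write_probe_annotation(ann, out_dir / "annotation.csv"),
    }
    tsg_path = out_dir / "tsg_synthetic.txt"
    tsg_path.write_text("\n".join(tsg) + "\n")
    paths["tsg"] = tsg_path
    panel_path = out_dir / "lump_panel_synthetic.txt"
    panel_path.write_text("\n".join(panel) + "\n")
    paths["lump_panel"] = panel_path
    informative_path = out_dir / "informative_probes.txt"
    informative_path.write_text("\n".join(cohort.informative_probes) + "\n")
    paths["informative"] = informative_path
    return paths
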