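"""Synthetic family-structured methylation studies with planted regions.

The generator emulates the evaluation design of a family EWAS cohort:
related samples (trios or sibships) with a heritable quantitative
phenotype, covariates (age, sex, study center, smoking status), and
block-correlated methylation probes grouped into annotated regions, a
subset of which carry a planted phenotype effect.

M-values are generated directly — per region a draw from a multivariate
normal with exchangeable or AR(1) correlation, plus ``effect * phenotype``
on causal probes — and converted to beta values through the inverse
logit2 transform, so the generative correlation lives on the scale the
region statistic uses.  The phenotype is

    y = covariate effects + a + e,  a ~ N(0, h2 * 2*phi),  e ~ N(0, 1 - h2),

i.e. a polygenic family random effect with heritability ``h2`` on a
unit-variance scale, mirroring a heritable trait such as log
triglycerides.  Everything is reproducible from the config seed;
replicate experiments spawn independent child seeds deterministically.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (KinshipMatrix, MethylationMatrix, ProbeManifest, SampleTable,
                 write_kinship, write_methylation)
from .preprocess import beta_to_m, m_to_beta
from .ewas import fit_probe_lmm, run_ewas
from .regions import attach_regions, build_gene_regions, build_island_regions
from .stats import run_globalp

__all__ = ["SimulationConfig", "SimulatedStudy", "simulate_study",
           "write_study", "read_study", "type_one_error_experiment",
           "power_experiment", "fixed_effect_recovery_experiment"]

#: covariate generation/effect defaults: realistic mid-life cohort mix
_COVARIATE_DEFAULTS = {
    "age": {"mean": 48.0, "sd": 12.0, "effect": 0.005},
    "sex": {"levels": ("F", "M"), "p": (0.5, 0.5), "effects": {"M": 0.2}},
    "center": {"levels": ("MN", "UT"), "p": (0.5, 0.5), "effects": {"UT": 0.1}},
    "smoking": {"levels": ("never", "former", "current"),
                "p": (0.55, 0.25, 0.20),
                "effects": {"former": 0.1, "current": 0.25}},
}


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_study`.

    ``family_structure`` is one of ``"unrelated"``, ``"trio"`` (two
    founder parents + one child) or ``"sibs<k>"`` (two founders + k full
    sibs, e.g. ``"sibs3"``).  ``causal_regions`` lists
    ``(region_index, per-probe effect on M per unit phenotype)`` pairs.
    ``h2`` is the phenotype heritability carried by the kinship random
    effect; ``rho`` the within-region probe correlation under the chosen
    ``correlation_model`` (``"exchangeable"`` or ``"ar1"``).
    """

    seed: int
    n_families: int = 200
    family_structure: str = "unrelated"
    n_regions: int = 10
    probes_per_region: int = 5
    correlation_model: str = "exchangeable"
    rho: float = 0.6
    n_null_singletons: int = 0
    causal_regions: tuple = ()
    h2: float = 0.4
    noise_sd: float = 1.0
    covariate_spec: dict = field(default_factory=lambda: _COVARIATE_DEFAULTS)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must be in [0, 1)")
        if self.probes_per_region < 1:
            raise ValueError("probes_per_region must be >= 1")
        if self.n_regions < 0 or self.n_families < 1:
            raise ValueError("n_regions must be >= 0 and n_families >= 1")
        if self.correlation_model not in ("exchangeable", "ar1"):
            raise ValueError(f"unknown correlation model {self.correlation_model!r}")
        self.causal_regions = tuple((int(i), float(e)) for i, e in self.causal_regions)
        for i, e in self.causal_regions:
            if not 0 <= i < self.n_regions:
                raise ValueError(f"causal region index {i} out of range")
            if not np.isfinite(e):
                raise ValueError("causal effect sizes must be finite")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulatedStudy:
    """A complete synthetic study plus the ground truth of planted effects."""

    meth: MethylationMatrix          # beta values
    samples: SampleTable
    kinship: KinshipMatrix
    manifest: ProbeManifest
    truth: pd.DataFrame              # region_id, effect, probe_ids
    config: SimulationConfig


# ---------------------------------------------------------------------------
# family structure
# ---------------------------------------------------------------------------

def _family_blocks(structure: str) -> tuple[int, np.ndarray]:
    """(family size, within-family 2*phi block) for a structure name."""
    if structure == "unrelated":
        return 1, np.array([[1.0]])
    if structure == "trio":
        # father, mother, child
        A = np.array([[1.0, 0.0, 0.5],
                      [0.0, 1.0, 0.5],
                      [0.5, 0.5, 1.0]])
        return 3, A
    if structure.startswith("sibs"):
        k = int(structure[4:])
        if k < 1:
            raise ValueError("sibs structure needs at least one sib")
        size = k + 2
        A = np.full((size, size), 0.0)
        A[:2, :2] = np.eye(2)
        A[2:, :2] = 0.5
        A[:2, 2:] = 0.5
        A[2:, 2:] = np.full((k, k), 0.5) + 0.5 * np.eye(k)
        return size, A
    raise ValueError(f"unknown family structure {structure!r}")


def _build_kinship(config: SimulationConfig) -> tuple[KinshipMatrix, list, list]:
    size, A = _family_blocks(config.family_structure)
    n = size * config.n_families
    ids, fams = [], []
    for f in range(config.n_families):
        for k in range(size):
            ids.append(f"fam{f:04d}_i{k}")
            fams.append(f"fam{f:04d}")
    phi = np.zeros((n, n))
    for f in range(config.n_families):
        s = f * size
        phi[s:s + size, s:s + size] = A / 2.0
    return KinshipMatrix(tuple(ids), phi, check=False), ids, fams


# ---------------------------------------------------------------------------
# study generation
# ---------------------------------------------------------------------------

def _region_corr(m: int, rho: float, model: str) -> np.ndarray:
    if model == "exchangeable":
        S = np.full((m, m), rho)
        np.fill_diagonal(S, 1.0)
    else:  # ar1
        idx = np.arange(m)
        S = rho ** np.abs(idx[:, None] - idx[None, :])
    return S


def simulate_study(config: SimulationConfig,
                   kinship: KinshipMatrix | None = None) -> SimulatedStudy:
    """Generate one synthetic study; see the module docstring for the model.

    ``kinship`` may be passed in to reuse the (structure-determined)
    matrix across replicates; it must match the configured structure.
    """
    rng = np.random.default_rng(config.seed)
    size, A_block = _family_blocks(config.family_structure)
    if kinship is None:
        kinship, ids, fams = _build_kinship(config)
    else:
        ids = list(kinship.sample_ids)
        if len(ids) != size * config.n_families:
            raise ValueError("supplied kinship does not match the configured "
                             "family structure")
        fams = [i.rsplit("_", 1)[0] for i in ids]
    n = len(ids)

    # covariates
    spec = config.covariate_spec
    cols: dict[str, np.ndarray] = {}
    age = rng.normal(spec["age"]["mean"], spec["age"]["sd"], size=n)
    cols["age"] = np.round(age, 1)
    for name in ("sex", "center", "smoking"):
        s = spec[name]
        cols[name] = rng.choice(s["levels"], size=n, p=s["p"])

    # phenotype: covariate effects + family polygenic effect + residual
    y = spec["age"]["effect"] * (cols["age"] - spec["age"]["mean"])
    for name in ("sex", "center", "smoking"):
        s = spec[name]
        for lev, eff in s["effects"].items():
            y = y + eff * (cols[name] == lev)
    if config.h2 > 0:
        L = np.linalg.cholesky(config.h2 * A_block + 1e-12 * np.eye(size))
        a = (L @ rng.standard_normal((size, config.n_families))).T.ravel()
    else:
        a = np.zeros(n)
    y = y + a + rng.normal(0.0, np.sqrt(1.0 - config.h2), size=n)

    samples = SampleTable(
        pd.DataFrame({"phenotype": y, **cols,
                      "family_id": fams}, index=pd.Index(ids, name="sample_id")),
        phenotype="phenotype", covariates=("age", "sex", "center", "smoking"),
        family="family_id")

    # methylation M-values: correlated blocks per region (+ singletons)
    effects = dict(config.causal_regions)
    m = config.probes_per_region
    L_region = np.linalg.cholesky(
        _region_corr(m, config.rho, config.correlation_model)
        + 1e-12 * np.eye(m)) if m > 1 else np.ones((1, 1))
    probe_rows, probe_ids, man_rows = [], [], []
    truth_rows = []
    for r in range(config.n_regions):
        base = config.noise_sd * (L_region @ rng.standard_normal((m, n)))
        eff = effects.get(r, 0.0)
        if eff != 0.0:
            base = base + eff * y[None, :]
        pos0 = 1_000_000 + r * 100_000
        ids_r = [f"cgr{r:04d}p{i:02d}" for i in range(m)]
        for i, pid in enumerate(ids_r):
            probe_ids.append(pid)
            probe_rows.append(base[i])
            man_rows.append({"probe_id": pid, "chrom": "1", "pos": pos0 + 200 * i,
                             "gene_names": (f"GENE{r:04d}",),
                             "gene_groups": ("Body",),
                             "island_relation": "none", "island_name": ""})
        truth_rows.append({"region_id": f"GENE{r:04d}:Body", "effect": eff,
                           "probe_ids": ";".join(ids_r)})
    for jx in range(config.n_null_singletons):
        pid = f"cgs{jx:05d}"
        probe_ids.append(pid)
        probe_rows.append(config.noise_sd * rng.standard_normal(n))
        man_rows.append({"probe_id": pid, "chrom": "1",
                         "pos": 50_000_000 + 10_000 * jx,
                         "gene_names": (), "gene_groups": (),
                         "island_relation": "none", "island_name": ""})

    M = np.vstack(probe_rows) if probe_rows else np.empty((0, n))
    betas = m_to_beta(M)
    meth = MethylationMatrix(pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"),
                                          columns=ids))
    man = pd.DataFrame(man_rows).set_index("probe_id") if man_rows else pd.DataFrame(
        columns=["chrom", "pos", "gene_names", "gene_groups",
                 "island_relation", "island_name"])
    manifest = ProbeManifest(man)
    truth = pd.DataFrame(truth_rows, columns=["region_id", "effect", "probe_ids"])
    return SimulatedStudy(meth, samples, kinship, manifest, truth, config)


# ---------------------------------------------------------------------------
# study directory round-trip (CLI `simulate` output, `run-all` input)
# ---------------------------------------------------------------------------

STUDY_FILES = {"meth": "methylation.tsv", "samples": "samples.tsv",
               "manifest": "manifest.tsv", "kinship": "kinship.csv",
               "truth": "truth.tsv", "config": "config.yaml"}


def write_study(study: SimulatedStudy, outdir: str) -> dict:
    """Write a complete study directory (all plain-text tables)."""
    import yaml

    os.makedirs(outdir, exist_ok=True)
    paths = {k: os.path.join(outdir, v) for k, v in STUDY_FILES.items()}
    write_methylation(study.meth, paths["meth"])
    study.samples.data.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    man = study.manifest.data.copy()
    out = pd.DataFrame({
        "IlmnID": man.index,
        "CHR": man["chrom"].to_numpy(),
        "MAPINFO": man["pos"].to_numpy(),
        "UCSC_RefGene_Name": [";".join(t) for t in man["gene_names"]],
        "UCSC_RefGene_Group": [";".join(t) for t in man["gene_groups"]],
        "Relation_to_UCSC_CpG_Island": [r if r != "none" else ""
                                        for r in man["island_relation"]],
        "UCSC_CpG_Islands_Name": man["island_name"].to_numpy(),
    })
    out.to_csv(paths["manifest"], sep="\t", index=False)
    write_kinship(study.kinship, paths["kinship"])
    study.truth.to_csv(paths["truth"], sep="\t", index=False)
    cfg = dataclasses.asdict(study.config)
    cfg["causal_regions"] = [list(c) for c in cfg["causal_regions"]]
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


def read_study(outdir: str):
    """Read back a study directory written by :func:`write_study`."""
    from . import io as gio

    paths = {k: os.path.join(outdir, v) for k, v in STUDY_FILES.items()}
    meth = gio.read_methylation(paths["meth"])
    samples = gio.read_samples(paths["samples"], phenotype="phenotype",
                               covariates=("age", "sex", "center", "smoking"),
                               family="family_id")
    manifest = gio.read_manifest(paths["manifest"])
    kinship = gio.read_kinship(paths["kinship"])
    truth = pd.read_csv(paths["truth"], sep="\t")
    return meth, samples, manifest, kinship, truth


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _child_seeds(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def _auto_model(config: SimulationConfig) -> str:
    return "ols" if config.family_structure == "unrelated" else "lmm"


def _run_pipeline_once(study: SimulatedStudy, alpha: float, model: str,
                       min_probes: int = 2):
    kin = None if model == "ols" else study.kinship
    ewas = run_ewas(study.meth, study.samples, kin, model=model)
    gene_set, _ = build_gene_regions(study.manifest)
    island_set, _ = build_island_regions(study.manifest)
    regions, _ = attach_regions(gene_set, island_set, min_probes=min_probes)
    table, _ = run_globalp(ewas, regions, study.meth, study.samples, alpha=alpha,
                           min_probes=min_probes)
    return ewas, table


def type_one_error_experiment(config: SimulationConfig, n_reps: int,
                              alpha: float = 0.05,
                              model: str | None = None) -> dict:
    """Empirical null rejection rates of the full pipeline.

    Runs simulate -> EWAS -> region test for ``n_reps`` independent
    replicates of a configuration with *no* causal regions, and reports
    the fraction of region tests (and probe tests) with p < alpha, with
    a binomial 95% Monte-Carlo confidence interval.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if any(e != 0.0 for _, e in config.causal_regions):
        raise ValueError("type-I experiment requires a null configuration "
                         "(no causal regions)")
    model = model or _auto_model(config)
    kinship, _, _ = _build_kinship(config)
    region_hits = region_total = 0
    probe_hits = probe_total = 0
    for seed in _child_seeds(config.seed, n_reps):
        study = simulate_study(config.replace(seed=seed), kinship=kinship)
        ewas, table = _run_pipeline_once(study, alpha, model)
        region_hits += int((table["p_value"] < alpha).sum())
        region_total += len(table)
        pvals = ewas.loc[ewas["converged"].astype(bool), "p_value"]
        probe_hits += int((pvals < alpha).sum())
        probe_total += len(pvals)

    def _ci(h, t):
        if t == 0:
            return (float("nan"), float("nan"))
        rate = h / t
        half = 1.96 * np.sqrt(max(rate * (1 - rate), 1e-12) / t)
        return (rate - half, rate + half)

    return {
        "alpha": alpha, "n_reps": n_reps, "model": model,
        "region_rate": region_hits / region_total if region_total else float("nan"),
        "region_ci": _ci(region_hits, region_total),
        "n_region_tests": region_total,
        "probe_rate": probe_hits / probe_total if probe_total else float("nan"),
        "probe_ci": _ci(probe_hits, probe_total),
        "n_probe_tests": probe_total,
    }


def power_experiment(config: SimulationConfig, effect_grid, n_reps: int,
                     alpha: float = 0.05, model: str | None = None) -> pd.DataFrame:
    """Power of the region test across a grid of planted effect sizes.

    ``config`` must name at least one causal region; for each effect in
    the grid every causal region's per-probe effect is set to that value
    and the fraction of replicates in which a causal region is detected
    is recorded — both by raw region p < alpha (``power_p``; at effect 0
    this is the type-I error) and by BH q < alpha (``power_q``, detection
    after multiplicity correction).  A binomial SE column supports
    monotone-trend checks.
    """
    if not config.causal_regions:
        raise ValueError("power experiment requires at least one causal region")
    model = model or _auto_model(config)
    kinship, _, _ = _build_kinship(config)
    causal_idx = [i for i, _ in config.causal_regions]
    causal_ids = {f"GENE{i:04d}:Body" for i in causal_idx}
    effect_grid = list(effect_grid)
    rows = []
    grid_seeds = _child_seeds(config.seed, len(effect_grid))
    for eff, gseed in zip(effect_grid, grid_seeds):
        cfg = config.replace(causal_regions=tuple((i, float(eff)) for i in causal_idx),
                             seed=gseed)
        hit_p = hit_q = total = 0
        for seed in _child_seeds(gseed, n_reps):
            study = simulate_study(cfg.replace(seed=seed), kinship=kinship)
            _, table = _run_pipeline_once(study, alpha, model)
            sub = table[table["region_id"].isin(causal_ids)]
            hit_p += int((sub["p_value"] < alpha).sum())
            hit_q += int((sub["q_value"] < alpha).sum())
            total += len(causal_ids)
        power_p = hit_p / total
        power_q = hit_q / total
        rows.append({"effect": float(eff), "power_p": power_p, "power_q": power_q,
                     "n_tests": total,
                     "se_p": float(np.sqrt(max(power_p * (1 - power_p), 1e-12) / total)),
                     "se_q": float(np.sqrt(max(power_q * (1 - power_q), 1e-12) / total))})
    return pd.DataFrame(rows)


def fixed_effect_recovery_experiment(effect: float = 0.5, n_families: int = 300,
                                     structure: str = "trio", h2: float = 0.4,
                                     n_reps: int = 500, seed: int = 0) -> dict:
    """Unbiasedness check for the mixed-model EWAS coefficient.

    Each replicate simulates a family study with a single causal probe of
    known per-unit effect on M, fits the kinship mixed model, and records
    the estimate and its model SE.  Reports the mean estimate, its
    Monte-Carlo SEM, the empirical SD of estimates and the mean model SE
    (the last two should agree if the SEs are honest).
    """
    cfg = SimulationConfig(seed=seed, n_families=n_families,
                           family_structure=structure, n_regions=1,
                           probes_per_region=1, causal_regions=((0, effect),),
                           h2=h2)
    kinship, _, _ = _build_kinship(cfg)
    d, U = kinship.eig()  # warm the cache shared across replicates
    est, ses = [], []
    for s in _child_seeds(seed, n_reps):
        study = simulate_study(cfg.replace(seed=s), kinship=kinship)
        m_vec = beta_to_m(study.meth.values, clamp=True)[0]
        rec = fit_probe_lmm(m_vec, study.samples, kinship, probe_id="causal")
        est.append(rec.beta_hat)
        ses.append(rec.se)
    est = np.asarray(est)
    ses = np.asarray(ses)
    return {
        "effect": effect, "n_reps": n_reps,
        "mean_beta_hat": float(est.mean()),
        "sem": float(est.std(ddof=1) / np.sqrt(n_reps)),
        "empirical_se": float(est.std(ddof=1)),
        "mean_model_se": float(ses.mean()),
        "bias": float(est.mean() - effect),
    }
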