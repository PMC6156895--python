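"""End-to-end orchestration: filter -> EWAS -> regions -> region test."""

from __future__ import annotations

import pandas as pd

from .io import (KinshipMatrix, MethylationMatrix, ProbeManifest, SampleTable,
                 align_samples)
from .preprocess import ExclusionList, filter_probes
from .ewas import run_ewas
from .regions import RegionSet, attach_regions, build_gene_regions, build_island_regions
from .stats import run_globalp, DEFAULT_EIG_TOL

__all__ = ["run_pipeline"]


def run_pipeline(
    meth: MethylationMatrix,
    samples: SampleTable,
    manifest: ProbeManifest,
    kinship: KinshipMatrix | None = None,
    exclusions: tuple[ExclusionList, ...] = (),
    model: str = "auto",
    alpha: float = 0.05,
    min_probes: int = 2,
    max_probes: int | None = None,
    eig_tol: float = DEFAULT_EIG_TOL,
    custom_regions: RegionSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the whole DMR analysis and return (ewas_table, dmr_table, audit).

    ``model='auto'`` picks the kinship mixed model when a kinship matrix
    is supplied and OLS otherwise.  ``custom_regions`` bypasses manifest
    region construction (user-supplied region file).  Deterministic given
    identical inputs.
    """
    if model == "auto":
        model = "lmm" if kinship is not None else "ols"
    audit: dict = {}

    retained, filter_audit = filter_probes(manifest, exclusions)
    audit["filter"] = filter_audit
    keep = [p for p in map(str, meth.probe_ids) if p in set(retained)]
    meth = meth.subset_probes(keep)

    meth, samples, kinship, align_report = align_samples(meth, samples, kinship)
    audit["alignment"] = align_report

    ewas = run_ewas(meth, samples, kinship, model=model)

    if custom_regions is not None:
        regions = custom_regions
        audit["regions"] = {"n_regions": len(regions), "source": "custom"}
    else:
        gene_set, gene_audit = build_gene_regions(manifest, retained=keep)
        island_set, island_audit = build_island_regions(manifest, retained=keep)
        regions, attach_audit = attach_regions(gene_set, island_set,
                                               min_probes=min_probes,
                                               max_probes=max_probes)
        audit["regions"] = {"gene": gene_audit, "island": island_audit,
                            "attach": attach_audit}

    dmr, dmr_audit = run_globalp(ewas, regions, meth, samples, alpha=alpha,
                                 min_probes=min_probes, eig_tol=eig_tol)
    audit["globalp"] = dmr_audit
    return ewas, dmr, audit
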