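# globalp

Annotation-based detection of **differentially methylated regions (DMRs)**
from methylation-array data, for studies — including family studies — of
quantitative traits.

Single-probe EWAS (epigenome-wide association study) analyses ignore the
information carried by neighboring, correlated CpG probes. `globalp` tests
*regions* instead: probes are grouped by fixed biological annotation —
six gene functional categories (TSS1500, TSS200, 5′UTR, 1stExon, Body,
3′UTR) and five CpG-island relation categories (Island, N/S Shore,
N/S Shelf) — and each region is tested jointly.

## The statistic

For a region with *m* probes, let **z** = (β̂₁/SE₁, …, β̂ₘ/SEₘ) be the
per-probe EWAS z-scores. Under the null, **z** ~ MVN(0, Σ), where Σ is
the correlation matrix of the probes' M-values in the study sample —
the *partial* correlation matrix (after residualizing covariates) when
covariates are in the model. Hence

&nbsp;&nbsp;&nbsp;&nbsp; **z**ᵀ Σ⁻¹ **z** ~ χ²ₘ.

Σ is estimated per region from individual-level data; an
eigenvalue-truncated pseudo-inverse handles collinear probes (df drops
to the retained rank). Because annotations overlap, the region family
is corrected with Benjamini–Hochberg FDR (default cutoff 0.05) rather
than Bonferroni.

The package also provides:

- the **EWAS stage** itself: per-probe linear models of methylation
  M-values (M = log₂(β/(1−β))) on the phenotype plus covariates, as OLS
  for unrelated samples or a **kinship linear mixed model** (REML, with
  random-effect covariance σ²g·2Φ from pedigree-derived kinship) for
  families;
- pedigree → kinship coefficients, probe exclusion filters, and all
  table I/O (methylation matrix, sample table, Illumina-style manifest,
  kinship/pedigree, results TSV + BED);
- a **simulator** of family-structured studies with block-correlated
  probes and planted region effects, plus calibration/power experiment
  drivers.

## Worked example

```python
from globalp import SimulationConfig, simulate_study, run_pipeline

config = SimulationConfig(seed=42, n_families=120, family_structure="trio",
                          n_regions=4, probes_per_region=5, rho=0.6,
                          causal_regions=((0, 0.4),), h2=0.4)
study = simulate_study(config)
ewas, dmr, audit = run_pipeline(study.meth, study.samples, study.manifest,
                                study.kinship)
print(dmr[["region_id", "n_probes", "statistic", "df", "p_value", "q_value"]])
```

prints (from `python examples/simulated_dmr_analysis.py`):

```
    region_id  n_probes  statistic  df  p_value  q_value  significant
GENE0000:Body         5        123   5 6.13e-25 2.45e-24         True
GENE0001:Body         5       8.69   5    0.122     0.17        False
GENE0002:Body         5       8.57   5    0.128     0.17        False
GENE0003:Body         5       2.51   5    0.776    0.776        False
```

The planted region (`GENE0000:Body`, per-probe effect 0.4 on M per
phenotype unit) yields a region χ² of 123 on 5 df and survives FDR; the
three null regions do not. More narrative scripts live in `examples/`.

## Command line

```bash
globalp simulate --seed 7 --out study/ --n-families 100 --causal 0:0.3
globalp run-all  --study study/ --out results/
# or stage by stage:
globalp filter --manifest manifest.tsv --exclude polymorphic.txt --out retained.txt
globalp ewas   --meth meth.tsv --samples samples.tsv --phenotype tg \
               --log-phenotype --covariate age --covariate sex \
               --pedigree ped.tsv --out ewas.tsv
globalp dmr    --ewas ewas.tsv --meth meth.tsv --samples samples.tsv \
               --phenotype tg --log-phenotype --covariate age --covariate sex \
               --manifest manifest.tsv --out dmr.tsv --bed dmr.bed
```

Result tables use 1-based inclusive coordinates; the BED export is
0-based half-open.

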