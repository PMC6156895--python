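"""Readers, writers and in-memory containers for methylation studies.

All external tables are plain TSV/CSV.  The in-memory containers are
thin dataclasses around :class:`pandas.DataFrame` / :class:`numpy.ndarray`
that check their invariants on construction:

* :class:`MethylationMatrix` — probe x sample beta values in [0, 1]
  (``NaN`` = missing);
* :class:`SampleTable` — one row per sample, a quantitative phenotype
  plus named covariates, with a deterministic design-matrix builder;
* :class:`ProbeManifest` — Illumina-manifest-style probe annotation
  (chromosome, 1-based position, gene name/group token lists, CpG-island
  name and relation);
* :class:`KinshipMatrix` — pairwise kinship coefficients ``phi``; the
  random-effect covariance used downstream is the additive relationship
  ``2*phi``.

Coordinates are 1-based inclusive internally (manifest convention);
:func:`write_results` converts to 0-based half-open only for BED export.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "SampleTable",
    "ProbeManifest",
    "KinshipMatrix",
    "ISLAND_RELATIONS",
    "read_methylation",
    "write_methylation",
    "read_samples",
    "read_manifest",
    "read_kinship",
    "read_pedigree",
    "align_samples",
    "write_results",
    "sha256sum",
]

#: closed set of CpG-island relation categories ("none" = not island-annotated)
ISLAND_RELATIONS = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf")

_RELATION_ALIASES = {r.lower(): r for r in ISLAND_RELATIONS}
_RELATION_ALIASES.update({"": "none", "none": "none", "nan": "none"})


def _infer_sep(path: str, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).lower().endswith(".csv") else "\t"


def sha256sum(path: str) -> str:
    """Hex SHA-256 of a file, for provenance logging."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# MethylationMatrix
# ---------------------------------------------------------------------------

@dataclass
class MethylationMatrix:
    """Probe x sample matrix of methylation beta values (fractions in [0, 1]).

    ``data`` is indexed by probe id with one column per sample id; missing
    values are ``NaN`` and are propagated (downstream operations define
    their own complete-case policy).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & np.isfinite(vals)):
            i, j = np.argwhere(bad & np.isfinite(vals))[0]
            raise ValueError(
                "beta value out of [0, 1] at probe "
                f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}: {vals[i, j]}"
            )
        self.data = self.data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.data.loc[list(probe_ids)])

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.data[list(sample_ids)])


def read_methylation(
    path: str,
    sep: str | None = None,
    samples_in_rows: bool = False,
    allow_missing: bool = True,
) -> MethylationMatrix:
    """Read a beta-value matrix from TSV/CSV.

    The first column holds probe ids and the remaining columns samples
    (set ``samples_in_rows=True`` for the transposed layout).  Values
    outside [0, 1] and non-numeric cells are rejected with the offending
    cell named; empty cells become missing values when ``allow_missing``.
    """
    raw = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0, dtype=str)

    def _cell(x):
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return np.nan
        s = str(x).strip()
        if not s:
            return np.nan
        try:
            return float(s)  # Python's parser: correctly rounded, round-trips
        except ValueError:
            return None  # sentinel: non-numeric text

    conv = raw.apply(lambda col: col.map(_cell))
    bad = conv.apply(lambda col: col.map(lambda v: v is None))
    num = conv.apply(lambda col: col.map(lambda v: np.nan if v is None else v)).astype(float)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric beta value at probe {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    if not allow_missing and num.isna().to_numpy().any():
        i, j = np.argwhere(num.isna().to_numpy())[0]
        raise ValueError(
            f"missing beta value at probe {raw.index[i]!r}, sample {raw.columns[j]!r} "
            "(pass allow_missing=True to keep missing values)"
        )
    if samples_in_rows:
        num = num.T
    num.index = num.index.astype(str)
    num.columns = num.columns.astype(str)
    return MethylationMatrix(num)


def write_methylation(meth: MethylationMatrix, path: str, sep: str | None = None) -> None:
    """Write a beta matrix; values round-trip to full precision (17 sig. digits)."""
    meth.data.to_csv(path, sep=_infer_sep(path, sep), index_label="probe_id",
                     float_format=lambda v: format(v, ".17g"))


# ---------------------------------------------------------------------------
# SampleTable
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Phenotype + covariate table, indexed by sample id.

    ``phenotype`` names the quantitative trait column; ``covariates``
    the adjustment columns.  Categorical covariates are expanded to
    indicator columns deterministically (levels sorted as strings, first
    level dropped as reference) by :meth:`design_matrix`.
    """

    data: pd.DataFrame
    phenotype: str
    covariates: tuple[str, ...] = ()
    family: str | None = None

    def __post_init__(self) -> None:
        self.covariates = tuple(self.covariates)
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        for col in (self.phenotype, *self.covariates):
            if col not in self.data.columns:
                raise KeyError(f"column {col!r} not in sample table")
        if self.family is not None and self.family not in self.data.columns:
            raise KeyError(f"family column {self.family!r} not in sample table")
        pd.to_numeric(self.data[self.phenotype])  # must be numeric

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    def subset(self, sample_ids) -> "SampleTable":
        return SampleTable(self.data.loc[list(sample_ids)], self.phenotype,
                           self.covariates, self.family)

    def design_matrix(self, include_phenotype: bool = True) -> pd.DataFrame:
        """Fixed-effect design: intercept [+ phenotype] + expanded covariates.

        Numeric covariates enter as-is; categorical ones as 0/1 indicators
        for every non-reference level (sorted order, first level dropped).
        Rows with missing entries carry NaN so callers can take complete
        cases.
        """
        cols: dict[str, np.ndarray] = {"(intercept)": np.ones(len(self.data))}
        if include_phenotype:
            cols[self.phenotype] = self.data[self.phenotype].to_numpy(dtype=float)
        for c in self.covariates:
            s = self.data[c]
            if pd.api.types.is_numeric_dtype(s) and not pd.api.types.is_bool_dtype(s):
                cols[c] = s.to_numpy(dtype=float)
            else:
                miss = s.isna().to_numpy()
                levels = sorted(s.dropna().astype(str).unique())
                for lev in levels[1:]:
                    ind = (s.astype(str) == lev).to_numpy(dtype=float)
                    ind[miss] = np.nan
                    cols[f"{c}[{lev}]"] = ind
        return pd.DataFrame(cols, index=self.data.index)


def read_samples(
    path: str,
    phenotype: str,
    covariates=(),
    family: str | None = None,
    log_phenotype: bool = False,
    sep: str | None = None,
    id_column: str | None = None,
) -> SampleTable:
    """Read the sample table; optionally natural-log transform the phenotype."""
    df = pd.read_csv(path, sep=_infer_sep(path, sep))
    idc = id_column or df.columns[0]
    df = df.set_index(idc)
    df.index = df.index.astype(str)
    if log_phenotype:
        vals = pd.to_numeric(df[phenotype])
        if (vals <= 0).any():
            bad = df.index[vals <= 0][0]
            raise ValueError(f"phenotype {phenotype!r} must be positive for log transform "
                             f"(sample {bad!r})")
        df[phenotype] = np.log(vals)
    return SampleTable(df, phenotype, tuple(covariates), family)


# ---------------------------------------------------------------------------
# ProbeManifest
# ---------------------------------------------------------------------------

#: default column-name mapping (Illumina 450K manifest convention)
DEFAULT_MANIFEST_COLUMNS = {
    "probe_id": "IlmnID",
    "chrom": "CHR",
    "pos": "MAPINFO",
    "gene_names": "UCSC_RefGene_Name",
    "gene_groups": "UCSC_RefGene_Group",
    "island_relation": "Relation_to_UCSC_CpG_Island",
    "island_name": "UCSC_CpG_Islands_Name",
}


@dataclass
class ProbeManifest:
    """Probe annotation table indexed by probe id.

    Columns: ``chrom`` (str), ``pos`` (1-based int), ``gene_names`` /
    ``gene_groups`` (parallel token tuples split on ';'), ``island_name``
    (str or ''), ``island_relation`` (one of the five island categories
    or 'none').  Probes with no annotation are retained — they simply
    belong to no region.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe ids in manifest: {dups[:5]}")
        if (self.data["pos"] <= 0).any():
            bad = self.data.index[self.data["pos"] <= 0][0]
            raise ValueError(f"non-positive position for probe {bad!r}")
        for pid, names, groups in zip(self.data.index, self.data["gene_names"],
                                      self.data["gene_groups"]):
            if len(names) != len(groups):
                raise ValueError(
                    f"probe {pid!r}: gene_names has {len(names)} tokens but "
                    f"gene_groups has {len(groups)}"
                )

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    def positions(self, probe_ids) -> np.ndarray:
        return self.data.loc[list(probe_ids), "pos"].to_numpy(dtype=int)


def _tokenize(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ()
    s = str(value).strip()
    if not s:
        return ()
    return tuple(t.strip() for t in s.split(";"))


def read_manifest(path: str, sep: str | None = None,
                  columns: dict[str, str] | None = None) -> ProbeManifest:
    """Read an Illumina-manifest-style annotation table.

    ``columns`` maps the internal names (probe_id, chrom, pos, gene_names,
    gene_groups, island_relation, island_name) to the file's column names;
    defaults follow the Illumina 450K manifest.  Gene name/group fields
    are tokenized on ';' and island relations normalized to the closed
    five-category set (anything else, including blank, becomes 'none').
    """
    cmap = dict(DEFAULT_MANIFEST_COLUMNS)
    if columns:
        cmap.update(columns)
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str)
    for key in ("probe_id", "chrom", "pos"):
        if cmap[key] not in df.columns:
            raise KeyError(f"manifest is missing required column {cmap[key]!r}")
    out = pd.DataFrame(index=df[cmap["probe_id"]].astype(str))
    out.index.name = "probe_id"
    out["chrom"] = df[cmap["chrom"]].astype(str).to_numpy()
    out["pos"] = pd.to_numeric(df[cmap["pos"]]).astype(int).to_numpy()

    def opt(key):
        col = cmap[key]
        return df[col] if col in df.columns else pd.Series([""] * len(df))

    out["gene_names"] = [_tokenize(v) for v in opt("gene_names")]
    out["gene_groups"] = [_tokenize(v) for v in opt("gene_groups")]
    rel = []
    for v in opt("island_relation"):
        key = ("" if v is None or (isinstance(v, float) and math.isnan(v)) else str(v)).strip().lower()
        rel.append(_RELATION_ALIASES.get(key, "none"))
    out["island_relation"] = rel
    out["island_name"] = ["" if (isinstance(v, float) and math.isnan(v)) or v is None
                          else str(v).strip() for v in opt("island_name")]
    return ProbeManifest(out)


# ---------------------------------------------------------------------------
# KinshipMatrix
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Pairwise kinship coefficients phi for a set of samples.

    ``phi[i, i] = 0.5`` for a non-inbred individual; off-diagonal entries
    lie in [0, 0.5].  The additive relationship matrix ``2*phi`` is the
    random-effect covariance used by the mixed model; it must be positive
    semidefinite (checked with an eigenvalue floor on construction).
    The eigendecomposition of ``2*phi`` is cached because the EWAS reuses
    it for every probe.
    """

    sample_ids: tuple
    phi: np.ndarray
    check: bool = True
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.sample_ids = tuple(str(s) for s in self.sample_ids)
        self.phi = np.asarray(self.phi, dtype=float)
        n = len(self.sample_ids)
        if self.phi.shape != (n, n):
            raise ValueError(f"phi shape {self.phi.shape} does not match {n} sample ids")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in kinship matrix")
        if self.check:
            if not np.allclose(self.phi, self.phi.T, atol=1e-8):
                raise ValueError("kinship matrix is not symmetric")
            if np.any(np.diag(self.phi) < 0.5 - 1e-8):
                raise ValueError("kinship diagonal below 0.5 (self-kinship of a "
                                 "non-inbred individual is 0.5)")
            off = self.phi - np.diag(np.diag(self.phi))
            if off.min() < -1e-8 or off.max() > 0.5 + 1e-8:
                raise ValueError("off-diagonal kinship outside [0, 0.5]")
            w = np.linalg.eigvalsh(2.0 * self.phi)
            if w.min() < -1e-8 * max(w.max(), 1.0):
                raise ValueError("2*phi is not positive semidefinite")

    @property
    def relationship(self) -> np.ndarray:
        """Additive relationship matrix 2*phi."""
        return 2.0 * self.phi

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition (eigenvalues, eigenvectors) of 2*phi."""
        if self._eig is None:
            d, u = np.linalg.eigh(2.0 * self.phi)
            self._eig = (np.clip(d, 0.0, None), u)
        return self._eig

    def subset(self, sample_ids) -> "KinshipMatrix":
        wanted = [str(s) for s in sample_ids]
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in pos]
        if missing:
            raise KeyError(f"samples not in kinship matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in wanted])
        return KinshipMatrix(tuple(wanted), self.phi[np.ix_(idx, idx)], check=False)

    @classmethod
    def identity(cls, sample_ids) -> "KinshipMatrix":
        """Kinship of mutually unrelated, non-inbred samples (phi = 0.5 I)."""
        n = len(sample_ids)
        return cls(tuple(sample_ids), 0.5 * np.eye(n), check=False)


def read_kinship(path: str, sep: str | None = None) -> KinshipMatrix:
    """Read a precomputed square kinship matrix (CSV with id header)."""
    df = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValueError("kinship matrix row and column ids differ")
    return KinshipMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_kinship(kin: KinshipMatrix, path: str) -> None:
    pd.DataFrame(kin.phi, index=list(kin.sample_ids),
                 columns=list(kin.sample_ids)).to_csv(path)


def read_pedigree(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a pedigree table.

    Accepts three columns (individual, father, mother) or four
    (family, individual, father, mother).  '0', '.', 'NA' and blank mean
    'founder'.  Returns a normalized frame with columns
    family/id/father/mother (father/mother empty string for founders).
    """
    df = pd.read_csv(path, sep=_infer_sep(path, sep), dtype=str).fillna("")
    if df.shape[1] == 3:
        df.insert(0, "family", "")
    elif df.shape[1] != 4:
        raise ValueError("pedigree must have 3 or 4 columns "
                         "(family, individual, father, mother)")
    df.columns = ["family", "id", "father", "mother"]
    for col in ("father", "mother"):
        df[col] = df[col].str.strip().replace({"0": "", ".": "", "NA": ""})
    df["id"] = df["id"].str.strip()
    if df["id"].duplicated().any():
        raise ValueError("duplicate individual ids in pedigree")
    return df


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_samples(
    meth: MethylationMatrix,
    samples: SampleTable,
    kinship: KinshipMatrix | None = None,
):
    """Restrict all inputs to the common sample set, in sorted-id order.

    Returns ``(meth, samples, kinship, report)`` where ``report`` gives
    the number of samples dropped from each input.  Deterministic: the
    aligned order is the sorted common ids, regardless of input order.
    """
    common = set(map(str, meth.sample_ids)) & set(map(str, samples.sample_ids))
    if kinship is not None:
        common &= set(kinship.sample_ids)
    if not common:
        raise ValueError("no samples in common between inputs")
    order = sorted(common)
    report = {
        "n_common": len(order),
        "dropped_methylation": meth.shape[1] - len(order),
        "dropped_samples": len(samples.sample_ids) - len(order),
        "dropped_kinship": (len(kinship.sample_ids) - len(order)) if kinship else 0,
    }
    meth_a = meth.subset_samples(order)
    samp_a = samples.subset(order)
    kin_a = kinship.subset(order) if kinship is not None else None
    return meth_a, samp_a, kin_a, report


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["chromosome", "start", "stop", "n_probes", "statistic",
                  "df", "p_value", "q_value", "region_id", "category"]


def write_results(table: pd.DataFrame, path: str, bed_path: str | None = None) -> None:
    """Write the DMR result table as TSV (and optionally BED6).

    The TSV keeps 1-based inclusive coordinates; the BED export converts
    to 0-based half-open (``bed_start = start - 1``).  The BED score is
    ``min(1000, round(-10 log10 p))``.
    """
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    extra = [c for c in table.columns if c not in cols]
    table[cols + extra].to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for _, row in table.iterrows():
                p = float(row["p_value"]) if np.isfinite(row["p_value"]) else 1.0
                score = int(min(1000, round(-10.0 * math.log10(max(p, 1e-300)))))
                fh.write(
                    f"{row['chromosome']}\t{int(row['start']) - 1}\t{int(row['stop'])}\t"
                    f"{row['region_id']}\t{score}\t.\n"
                )


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
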