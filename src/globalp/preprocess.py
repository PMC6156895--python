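"""Beta/M transforms and probe exclusion filters.

Beta values (fraction of methylated strands, in [0, 1]) are heteroskedastic
near the boundaries; association models therefore run on the M-value scale

    M = log2(beta / (1 - beta)),

which is the logit of beta in base 2.  Probes with design problems —
a polymorphic C/G or single-base-extension SNP at appreciable frequency,
or cross-reactive probes mapping to multiple genomic locations — are
removed before analysis.  Those criteria require external SNP/genome
resources, so they are consumed here as precomputed exclusion lists
rather than recomputed from sequence.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from collections import Counter
from typing import Iterable

import numpy as np

from .io import MethylationMatrix, ProbeManifest

__all__ = ["ExclusionList", "read_exclusion_list", "beta_to_m", "m_to_beta",
           "filter_probes"]

#: recognised exclusion reasons
REASONS = ("polymorphic", "cross_reactive", "user")


@dataclass
class ExclusionList:
    """A set of probe ids to drop, tagged with the reason for dropping."""

    probe_ids: frozenset
    reason: str = "user"

    def __post_init__(self):
        self.probe_ids = frozenset(str(p) for p in self.probe_ids)
        if self.reason not in REASONS:
            raise ValueError(f"unknown exclusion reason {self.reason!r}; "
                             f"expected one of {REASONS}")


def read_exclusion_list(path: str, reason: str | None = None) -> ExclusionList:
    """Read one probe id per line; infer the reason from the filename if unset."""
    if reason is None:
        name = os.path.basename(path).lower()
        if "polymorphic" in name or "snp" in name:
            reason = "polymorphic"
        elif "cross" in name:
            reason = "cross_reactive"
        else:
            reason = "user"
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return ExclusionList(frozenset(ids), reason)


def beta_to_m(beta, clamp: bool = True, eps: float = 1e-6):
    """Convert beta values to M-values, M = log2(beta / (1 - beta)).

    Array betas occasionally hit exactly 0 or 1, where M is infinite; by
    default such values are clamped to [eps, 1 - eps] first.  With
    ``clamp=False`` boundary values raise instead.  Accepts scalars,
    arrays or a :class:`MethylationMatrix` (missing values propagate).
    """
    if isinstance(beta, MethylationMatrix):
        out = beta.data.copy()
        out[:] = beta_to_m(beta.values, clamp=clamp, eps=eps)
        return out
    b = np.asarray(beta, dtype=float)
    boundary = (b == 0.0) | (b == 1.0)
    if boundary.any():
        if not clamp:
            raise ValueError("beta value exactly 0 or 1; enable clamping or "
                             "clean the input")
        b = np.clip(b, eps, 1.0 - eps)
    with np.errstate(invalid="ignore"):
        # log2(b) - log2(1-b) rather than log2(b/(1-b)): the antisymmetry
        # M(b) = -M(1-b) then holds exactly in floating point
        m = np.log2(b) - np.log2(1.0 - b)
    return float(m) if np.isscalar(beta) else m


def m_to_beta(m):
    """Inverse transform: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    # logistic in base 2, computed stably for large |M|:
    # beta = 1 / (1 + 2^-M) = 2^(-log2(1 + 2^-M))
    out = np.exp2(-np.logaddexp2(0.0, -arr))
    return float(out) if np.isscalar(m) else out


def filter_probes(manifest: ProbeManifest,
                  lists: Iterable[ExclusionList] = ()) -> tuple[list, dict]:
    """Drop excluded probes from the manifest's probe set.

    Returns ``(retained_ids, audit)``: retained ids in manifest order,
    and an audit dict with per-reason removal counts, the number of list
    ids absent from the manifest (``unmatched``, a no-op), and input /
    retained totals.  Set semantics: the result is independent of list
    order, and a probe named by several lists is removed once.
    """
    lists = list(lists)
    manifest_ids = [str(p) for p in manifest.probe_ids]
    present = set(manifest_ids)
    removed_by: dict[str, set] = {}
    unmatched = 0
    for lst in lists:
        hits = lst.probe_ids & present
        unmatched += len(lst.probe_ids - present)
        removed_by.setdefault(lst.reason, set()).update(hits)
    removed_all = set().union(*removed_by.values()) if removed_by else set()
    retained = [p for p in manifest_ids if p not in removed_all]
    audit = {reason: len(ids) for reason, ids in sorted(removed_by.items())}
    audit.update({
        "unmatched": unmatched,
        "n_input": len(manifest_ids),
        "n_removed": len(removed_all),
        "n_retained": len(retained),
    })
    return retained, audit
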