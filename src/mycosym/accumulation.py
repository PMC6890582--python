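"""Sample-based species accumulation and bootstrap richness extrapolation.

The accumulation curve is the exact (analytic) sample-based rarefaction

    S(m) = S_obs - sum_i C(N - n_i, m) / C(N, m)

over taxa i with incidence counts n_i out of N samples: the expected number
of taxa seen in a random subset of m samples.  Richness is extrapolated with
the incidence-based bootstrap estimator

    S_boot = S_obs + sum_i (1 - n_i / N)^N

and survey completeness is reported as coverage = 100 * S_obs / S_boot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "IncidenceTable",
    "incidence_from_records",
    "accumulation_curve",
    "bootstrap_richness",
    "coverage_percent",
]


@dataclass
class IncidenceTable:
    """Binary sample x taxon incidence."""

    M: np.ndarray  # samples x taxa
    sample_ids: list
    taxa: list

    def __post_init__(self):
        self.M = (np.asarray(self.M) > 0).astype(int)
        keep = self.M.sum(axis=0) > 0
        if not keep.all():
            self.M = self.M[:, keep]
            self.taxa = [t for t, k in zip(self.taxa, keep) if k]

    @property
    def n_samples(self) -> int:
        return self.M.shape[0]

    @property
    def s_obs(self) -> int:
        return self.M.shape[1]

    @property
    def incidence_counts(self) -> np.ndarray:
        return self.M.sum(axis=0)


def incidence_from_records(registry, records, lineage="Mucoromycotina",
                           include_singletons=True) -> IncidenceTable:
    """Sample x taxon incidence from occurrence records.

    Only colonized samples form rows (uncolonized samples carry no incidence
    information for taxon accumulation).  ``include_singletons`` toggles the
    two published-curve variants (delimited taxa only vs taxa + singletons).
    """
    sel = [
        r
        for r in records
        if r.fungal_lineage == lineage and (include_singletons or not r.is_singleton)
    ]
    if not sel:
        raise ValueError("no matching records")
    samples = sorted({r.sample_id for r in sel})
    taxa = sorted({r.fungal_taxon for r in sel})
    si = {s: i for i, s in enumerate(samples)}
    ti = {t: j for j, t in enumerate(taxa)}
    M = np.zeros((len(samples), len(taxa)), dtype=int)
    for r in sel:
        M[si[r.sample_id], ti[r.fungal_taxon]] = 1
    return IncidenceTable(M, samples, taxa)


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def accumulation_curve(table: IncidenceTable, m=None) -> pd.DataFrame:
    """Expected richness S(m) for m = 1..N (exact rarefaction).

    Monotone nondecreasing with S(N) = S_obs.  Raises for m > N.
    """
    N = table.n_samples
    if m is None:
        m = np.arange(1, N + 1)
    m = np.atleast_1d(m)
    if (m > N).any() or (m < 1).any():
        raise ValueError("m must be in 1..N")
    n_i = table.incidence_counts
    S = np.empty(len(m), dtype=float)
    for k, mm in enumerate(m):
        ok = (N - n_i) >= mm
        term = np.zeros(len(n_i))
        if ok.any():
            term[ok] = np.exp(_log_comb(N - n_i[ok], mm) - _log_comb(N, mm))
        S[k] = table.s_obs - term.sum()
    return pd.DataFrame({"m": m, "richness": S})


def bootstrap_richness(table: IncidenceTable) -> float:
    """Incidence-based bootstrap richness estimate."""
    N = table.n_samples
    n_i = table.incidence_counts
    return float(table.s_obs + ((1.0 - n_i / N) ** N).sum())


def coverage_percent(table: IncidenceTable) -> float:
    """Estimated percent of the taxon pool already detected."""
    s_boot = bootstrap_richness(table)
    if s_boot <= 0:
        raise ValueError("bootstrap richness must be positive")
    return 100.0 * table.s_obs / s_boot
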