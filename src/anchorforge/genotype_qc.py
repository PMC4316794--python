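"""F2 genotype matrix container and quality control.

Calls are codominant and coded by parental origin: ``A`` (homozygous for
the first parent), ``H`` (heterozygous), ``B`` (homozygous for the second
parent) and ``-`` (missing). Internally calls are stored as int8 with
``A=0, H=1, B=2, missing=-1``.

QC mirrors a standard array-genotyping workflow: individuals are dropped
on call rate, markers on cluster/call quality (``q1``/``q2``) and on the
number of observed genotype classes, and every marker is screened for
segregation distortion against the F2 1:2:1 expectation with a two-degree
of-freedom chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1
CODE_TO_INT = {"A": 0, "H": 1, "B": 2, "-": MISSING}
INT_TO_CODE = {v: k for k, v in CODE_TO_INT.items()}


class PipelineError(RuntimeError):
    """Raised when a QC step leaves nothing to analyse."""


@dataclass
class GenotypeData:
    """Markers x individuals call matrix plus per-marker metadata.

    ``calls`` is an int8 DataFrame indexed by marker id with individual ids
    as columns. ``marker_meta`` is indexed identically and carries at least
    ``scaffold``, ``pos``, ``q1`` and ``q2``; simulator-produced matrices
    additionally carry truth columns (``chrom``, ``chrom_pos``, ``cm``).
    """

    calls: pd.DataFrame
    marker_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not self.marker_meta.empty and not self.calls.index.equals(
            self.marker_meta.index
        ):
            self.marker_meta = self.marker_meta.loc[self.calls.index]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[1]

    def subset_markers(self, marker_ids) -> "GenotypeData":
        meta = (
            self.marker_meta.loc[marker_ids]
            if not self.marker_meta.empty
            else self.marker_meta
        )
        return GenotypeData(self.calls.loc[marker_ids], meta)

    def subset_individuals(self, individual_ids) -> "GenotypeData":
        return GenotypeData(self.calls[list(individual_ids)], self.marker_meta)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-marker counts of the A/H/B classes (missing excluded)."""
        vals = self.calls.to_numpy()
        out = pd.DataFrame(
            {
                "nA": (vals == 0).sum(axis=1),
                "nH": (vals == 1).sum(axis=1),
                "nB": (vals == 2).sum(axis=1),
            },
            index=self.calls.index,
        )
        return out

    # -- round-trippable TSV serialization --------------------------------

    def to_tsv(self, path) -> None:
        letters = self.calls.replace(INT_TO_CODE)
        df = pd.concat([self.marker_meta, letters], axis=1)
        df.index.name = "marker"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "GenotypeData":
        df = pd.read_csv(path, sep="\t", index_col="marker")
        call_cols = [c for c in df.columns if set(df[c].astype(str)) <= set("AHB-")]
        # metadata columns precede the individual columns
        meta_cols = [c for c in df.columns if c not in call_cols]
        calls = df[call_cols].apply(lambda s: s.map(CODE_TO_INT)).astype(np.int8)
        return cls(calls, df[meta_cols])


def filter_individuals(data: GenotypeData, min_call_rate: float = 0.85) -> GenotypeData:
    """Drop individuals whose call rate is <= ``min_call_rate`` (strict keep-above)."""
    if data.n_markers == 0 or data.n_individuals == 0:
        raise PipelineError("empty genotype matrix")
    rate = (data.calls.to_numpy() != MISSING).mean(axis=0)
    keep = rate > min_call_rate
    if not keep.any():
        raise PipelineError(
            f"all {data.n_individuals} individuals fail the call-rate "
            f"threshold {min_call_rate}"
        )
    return data.subset_individuals(data.calls.columns[keep])


def filter_markers(
    data: GenotypeData, min_q1: float = 0.4, min_q2: float = 0.2
) -> GenotypeData:
    """Keep markers with q1 > ``min_q1``, q2 > ``min_q2`` and >=2 observed
    genotype classes (monomorphic markers carry no mapping information)."""
    for col in ("q1", "q2"):
        if col not in data.marker_meta.columns:
            raise KeyError(f"marker_meta lacks required column {col!r}")
    counts = data.genotype_counts()
    n_classes = (counts.to_numpy() > 0).sum(axis=1)
    keep = (
        (data.marker_meta["q1"].to_numpy() > min_q1)
        & (data.marker_meta["q2"].to_numpy() > min_q2)
        & (n_classes >= 2)
    )
    return data.subset_markers(data.calls.index[keep])


def segregation_chi2(n_a: int, n_h: int, n_b: int,
                     alpha_extreme: float = 0.0001,
                     alpha_flag: float = 0.05) -> dict:
    """Chi-square test of observed (nA, nH, nB) against the 1:2:1 F2 ratio.

    df = 2, so the upper-tail p-value has the closed form exp(-chi2/2).
    Status is ``removed_extreme`` for p < alpha_extreme, ``flagged_distorted``
    for p < alpha_flag, otherwise ``kept``; boundary equality keeps the
    marker. Markers with zero informative calls get status ``no_data``.
    """
    n = n_a + n_h + n_b
    if n == 0:
        return {"nA": 0, "nH": 0, "nB": 0, "chi2": float("nan"),
                "p": float("nan"), "status": "no_data"}
    expected = np.array([0.25, 0.5, 0.25]) * n
    observed = np.array([n_a, n_h, n_b], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    if p < alpha_extreme:
        status = "removed_extreme"
    elif p < alpha_flag:
        status = "flagged_distorted"
    else:
        status = "kept"
    return {"nA": n_a, "nH": n_h, "nB": n_b, "chi2": chi2, "p": p, "status": status}


def segregation_report(data: GenotypeData,
                       alpha_extreme: float = 0.0001,
                       alpha_flag: float = 0.05) -> pd.DataFrame:
    """Segregation test for every marker; one row per marker."""
    counts = data.genotype_counts()
    rows = [
        segregation_chi2(r.nA, r.nH, r.nB, alpha_extreme, alpha_flag)
        for r in counts.itertuples()
    ]
    return pd.DataFrame(rows, index=counts.index)


def drop_extreme_distortion(data: GenotypeData, report: pd.DataFrame) -> GenotypeData:
    keep = ~report["status"].isin(["removed_extreme", "no_data"])
    return data.subset_markers(report.index[keep])


def prune_individuals_within_group(
    data: GenotypeData, group_markers, max_missing: float = 0.10
) -> GenotypeData:
    """Within one linkage group, drop individuals with a missing-call
    fraction over the group's markers strictly above ``max_missing``."""
    sub = data.calls.loc[list(group_markers)].to_numpy()
    frac_missing = (sub == MISSING).mean(axis=0)
    keep = frac_missing <= max_missing
    return data.subset_individuals(data.calls.columns[keep])
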