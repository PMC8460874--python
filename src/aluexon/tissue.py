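"""Tissue specificity of introns from an intron x sample read-count matrix.

Two tests combine into the tissue-specific call:

*presence* — an intron is present in a tissue when at least
``presence_sample_frac`` (default 15%) of that tissue's samples show
``presence_read_min`` (default 10) or more reads.

*absence* — a goodness-of-fit chi-square over tissues: the expected number of
samples lacking the intron is E_t = 0.85 * N_t per tissue; the observed O_t
is the number of samples with fewer than ``presence_read_min`` reads.  The
comparison is restricted to tissues with O_t >= E_t (absence not attributable
to sampling error alone), the statistic is sum (O-E)^2 / E with k-1 degrees
of freedom, and p = 1 when fewer than two tissues are retained.  A 2 x n
independence variant (absent/expressed counts per tissue) is available behind
a flag.

An intron is tissue specific for a target tissue when it is present in that
tissue and no other, and the absence test yields p <= alpha (default 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 1e-3


@dataclass
class TissueCountMatrix:
    """Read counts (introns x samples) with a sample -> tissue mapping."""

    counts: pd.DataFrame  # index: intron ids; columns: sample ids
    sample_tissue: Mapping[str, str]
    presence_read_min: int = 10
    presence_sample_frac: float = 0.15
    absence_expected_frac: float = 0.85

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.sample_tissue)
        if missing:
            raise ValueError(f"samples without a tissue assignment: {sorted(missing)[:5]}")
        if not (0 < self.presence_sample_frac <= 1 and 0 < self.absence_expected_frac <= 1):
            raise ValueError("fraction thresholds must lie in (0, 1]")
        if self.presence_read_min < 1:
            raise ValueError("presence_read_min must be >= 1")
        self._tissue_samples: dict[str, list[str]] = {}
        for s in self.counts.columns:
            self._tissue_samples.setdefault(self.sample_tissue[s], []).append(s)

    @property
    def tissues(self) -> list[str]:
        return sorted(self._tissue_samples)

    def samples_of(self, tissue: str) -> list[str]:
        try:
            return self._tissue_samples[tissue]
        except KeyError:
            raise KeyError(f"unknown tissue {tissue!r}") from None

    @classmethod
    def from_tsv(cls, matrix_path: str, sample_map_path: str, **kwargs) -> "TissueCountMatrix":
        """Load from a TSV matrix (intron_id + one column per sample) and a
        two-column sample -> tissue TSV."""
        counts = pd.read_csv(matrix_path, sep="\t", index_col=0)
        smap = pd.read_csv(sample_map_path, sep="\t", header=None, names=["sample", "tissue"])
        return cls(counts, dict(zip(smap["sample"], smap["tissue"])), **kwargs)


def presence_test(intron: str, tissue: str, matrix: TissueCountMatrix) -> bool:
    """Present iff >= presence_sample_frac of the tissue's samples carry
    >= presence_read_min reads (boundary inclusive: 15% passes at 15%)."""
    samples = matrix.samples_of(tissue)
    row = matrix.counts.loc[intron, samples]
    n_present = int((row >= matrix.presence_read_min).sum())
    return n_present / len(samples) >= matrix.presence_sample_frac


def absence_counts(intron: str, matrix: TissueCountMatrix) -> pd.DataFrame:
    """Per tissue: N samples, expected absent E = 0.85*N (unrounded), observed
    absent O (count < presence_read_min)."""
    rows = []
    for tissue in matrix.tissues:
        samples = matrix.samples_of(tissue)
        row = matrix.counts.loc[intron, samples]
        n = len(samples)
        rows.append(
            {
                "tissue": tissue,
                "n_samples": n,
                "expected_absent": matrix.absence_expected_frac * n,
                "observed_absent": int((row < matrix.presence_read_min).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def absence_test(intron: str, matrix: TissueCountMatrix, variant: str = "gof") -> float:
    """Chi-square absence p-value over tissues where O >= E.

    ``gof`` (default): statistic sum (O-E)^2/E, df = retained tissues - 1.
    ``independence``: chi-square test of independence on the retained 2 x k
    table of (absent, expressed) sample counts.
    Returns 1.0 when fewer than two tissues are retained (nothing to reject).
    """
    tab = absence_counts(intron, matrix)
    kept = tab[tab["observed_absent"] >= tab["expected_absent"]]
    if len(kept) < 2:
        return 1.0
    if variant == "gof":
        o = kept["observed_absent"].to_numpy(dtype=float)
        e = kept["expected_absent"].to_numpy(dtype=float)
        statistic = float(np.sum((o - e) ** 2 / e))
        return float(stats.chi2.sf(statistic, df=len(kept) - 1))
    if variant == "independence":
        absent = kept["observed_absent"].to_numpy(dtype=float)
        expressed = (kept["n_samples"] - kept["observed_absent"]).to_numpy(dtype=float)
        if expressed.sum() == 0 or absent.sum() == 0:
            return 1.0
        res = stats.chi2_contingency(np.vstack([absent, expressed]))
        return float(res.pvalue)
    raise ValueError(f"unknown absence-test variant {variant!r}")


def call_tissue_specific(
    intron: str,
    target_tissue: str,
    matrix: TissueCountMatrix,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "gof",
) -> bool:
    """Tissue specific iff present in exactly the target tissue and the
    absence test rejects at p <= alpha."""
    for tissue in matrix.tissues:
        present = presence_test(intron, tissue, matrix)
        if tissue == target_tissue:
            if not present:
                return False
        elif present:
            return False
    return absence_test(intron, matrix, variant=variant) <= alpha


def tissue_specific_table(
    matrix: TissueCountMatrix,
    target_tissue: str,
    alpha: float = DEFAULT_ALPHA,
    variant: str = "gof",
) -> pd.DataFrame:
    """Presence flags, absence p-value and verdict for every intron."""
    rows = []
    for intron in matrix.counts.index:
        presence = {t: presence_test(intron, t, matrix) for t in matrix.tissues}
        p = absence_test(intron, matrix, variant=variant)
        verdict = (
            presence.get(target_tissue, False)
            and sum(presence.values()) == 1
            and p <= alpha
        )
        row = {"intron": intron, "p_value": p, "tissue_specific": verdict}
        row.update({f"present_{t}": v for t, v in presence.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("intron")
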