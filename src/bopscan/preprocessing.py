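"""Sample- and probe-level quality control for beta / detection-p matrix pairs.

The filters operate on a background-subtracted beta matrix (probes x samples,
values in [0, 1]) together with its aligned detection p-value matrix:

1. a *sample* is dropped iff strictly more than ``frac`` of its probes have
   detection p above ``p_thresh`` (default 75% at 1e-5);
2. a *probe* is dropped if (rule 1) its detection p exceeds ``p_thresh``
   (default 0.05) in strictly more than ``frac`` of samples, then (rule 2) if
   it has any missing beta, then (rule 3) if it lies on chromosome X or Y.
   Rules apply sequentially, so each probe is attributed to the first rule
   that removes it and the per-rule counts are disjoint.

No normalisation is applied here: the pipeline starts from beta values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Beta and detection-p matrices do not share labels."""


def _check_aligned(beta: pd.DataFrame, detp: pd.DataFrame) -> None:
    if not beta.index.equals(detp.index) or not beta.columns.equals(detp.columns):
        raise AlignmentError("beta and detection-p matrices must share identical probe and sample labels")


@dataclass
class SampleQCReport:
    p_thresh: float
    frac: float
    failing_fraction: pd.Series  # per sample, fraction of probes failing detection
    dropped: list[str]

    def to_dict(self) -> dict:
        return {
            "p_thresh": self.p_thresh,
            "frac": self.frac,
            "failing_fraction": {k: float(v) for k, v in self.failing_fraction.items()},
            "dropped": list(self.dropped),
        }


def sample_qc(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    frac: float = 0.75,
    p_thresh: float = 1e-5,
) -> tuple[list[str], SampleQCReport]:
    """Return sample ids surviving the detection-rate filter, with a report.

    A sample is dropped iff strictly more than ``frac`` of its probes have
    detection p > ``p_thresh``.
    """
    _check_aligned(beta, detp)
    failing = (detp.to_numpy() > p_thresh).mean(axis=0)
    failing = pd.Series(failing, index=beta.columns, name="failing_fraction")
    keep = failing <= frac  # strict ">" to drop
    retained = list(beta.columns[keep])
    report = SampleQCReport(
        p_thresh=p_thresh,
        frac=frac,
        failing_fraction=failing,
        dropped=list(beta.columns[~keep]),
    )
    return retained, report


@dataclass
class ProbeQCReport:
    n_input: int
    n_retained: int
    removed_detection: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_sex_chrom: list[str] = field(default_factory=list)

    @property
    def counts(self) -> tuple[int, int, int]:
        return (
            len(self.removed_detection),
            len(self.removed_missing),
            len(self.removed_sex_chrom),
        )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "removed_detection": list(self.removed_detection),
            "removed_missing": list(self.removed_missing),
            "removed_sex_chrom": list(self.removed_sex_chrom),
            "counts": {
                "detection": len(self.removed_detection),
                "missing": len(self.removed_missing),
                "sex_chrom": len(self.removed_sex_chrom),
            },
        }


def probe_qc(
    beta: pd.DataFrame,
    detp: pd.DataFrame,
    annotations: pd.DataFrame,
    frac: float = 0.75,
    p_thresh: float = 0.05,
) -> tuple[pd.DataFrame, ProbeQCReport]:
    """Apply the three sequential probe filters; see module docstring.

    ``annotations`` must cover every probe in the matrix (needed for the
    sex-chromosome rule); a probe without annotation is a hard error.
    """
    _check_aligned(beta, detp)
    missing_annot = beta.index.difference(annotations.index)
    if len(missing_annot) > 0:
        raise KeyError(
            f"{len(missing_annot)} matrix probe(s) absent from annotations "
            f"(first: {missing_annot[0]}); cannot apply the sex-chromosome rule"
        )

    vals = beta.to_numpy(dtype=float)
    finite = np.isfinite(vals)
    if np.nanmin(np.where(finite, vals, 0.5)) < 0 or np.nanmax(np.where(finite, vals, 0.5)) > 1:
        raise ValueError("beta values must lie in [0, 1]")

    rule1 = (detp.to_numpy() > p_thresh).mean(axis=1) > frac
    rule2 = ~finite.all(axis=1) & ~rule1
    chroms = annotations.loc[beta.index, "chromosome"].astype(str).str.upper().to_numpy()
    rule3 = np.isin(chroms, ("X", "Y")) & ~rule1 & ~rule2

    keep = ~(rule1 | rule2 | rule3)
    filtered = beta.loc[keep]
    report = ProbeQCReport(
        n_input=len(beta),
        n_retained=int(keep.sum()),
        removed_detection=list(beta.index[rule1]),
        removed_missing=list(beta.index[rule2]),
        removed_sex_chrom=list(beta.index[rule3]),
    )
    return filtered, report
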