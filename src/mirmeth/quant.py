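"""RPM normalization and threshold calls: expressed, differential, methylated.

Counts are normalized to reads per million mapped miRNA reads (RPM); spike-in
rows share the denominator but are excluded from it.  Calls follow fixed
thresholds rather than model-based testing:

* expressed: >= 15 RPM in all control (scrambled) samples;
* down after knockdown: expressed in all controls and mean per-pair fold
  change strictly below 0.5 (strictly above 2 for up, with a secondary 1.5
  threshold reported alongside);
* methylated: >= 100 RPM in all anti-m6A IP replicates and mean
  (IP+1)/(IgG+1) enrichment of at least 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiffParams:
    min_rpm: float = 15.0
    down_fraction: float = 0.5
    up_fold: float = 2.0
    alt_fold: float = 1.5
    pseudocount: float = 1.0  # applied only when the control RPM is zero


@dataclass(frozen=True)
class RipParams:
    min_rpm: float = 100.0
    min_fold: float = 2.0
    pseudocount: float = 1.0  # RPM added to both sides of every ratio


def normalize_rpm(
    counts: pd.DataFrame, spike_names: Iterable[str] = ()
) -> pd.DataFrame:
    """Reads-per-million over the non-spike (miRNA) total of each sample.

    Spike rows are scaled by the same per-sample denominator but do not
    contribute to it.  A sample with zero mapped miRNA reads yields an
    all-zero column (with a logged warning) rather than NaNs.
    """
    spikes = [s for s in spike_names if s in counts.index]
    mirna = counts.drop(index=spikes)
    denom = mirna.sum(axis=0).astype(float)
    zero = denom == 0
    if zero.any():
        logger.warning(
            "samples with zero mapped miRNA reads: %s", list(denom.index[zero])
        )
    safe = denom.replace(0, np.nan)
    norm = counts.astype(float).mul(1e6).div(safe, axis=1)
    return norm.fillna(0.0)


def filter_expressed(
    norm: pd.DataFrame, samples: Sequence[str], min_rpm: float = 15.0
) -> list[str]:
    """References with at least ``min_rpm`` in *every* listed sample."""
    sub = norm[list(samples)]
    mask = (sub >= min_rpm).all(axis=1)
    return list(sub.index[mask])


def _pair_fold_change(
    treated: np.ndarray, control: np.ndarray, pseudocount: float
) -> np.ndarray:
    ctrl = np.where(control == 0, control + pseudocount, control)
    num = np.where(control == 0, treated + pseudocount, treated)
    return num / ctrl


def call_differential(
    norm: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    params: DiffParams = DiffParams(),
) -> pd.DataFrame:
    """Knockdown-response calls from (treated, control) sample pairs.

    Per-pair fold change is treated/control RPM (pseudocount applied when the
    control is zero).  A reference is *down* at fold threshold f when it has
    >= ``min_rpm`` RPM in every control and mean fold change < 1/f; *up* when
    it has >= ``min_rpm`` in every treated sample and mean fold change > f.
    Status is reported at both the primary (2.0) and secondary (1.5) folds.
    """
    for t, c in pairs:
        if t not in norm.columns or c not in norm.columns:
            raise ValueError(f"pair ({t!r}, {c!r}) not in matrix columns")
    treated = norm[[t for t, _ in pairs]].to_numpy()
    control = norm[[c for _, c in pairs]].to_numpy()
    fcs = _pair_fold_change(treated, control, params.pseudocount)
    mean_fc = fcs.mean(axis=1)
    sd_fc = fcs.std(axis=1, ddof=1) if fcs.shape[1] > 1 else np.zeros(len(fcs))
    ctrl_ok = (control >= params.min_rpm).all(axis=1)
    treat_ok = (treated >= params.min_rpm).all(axis=1)

    def status(fold: float) -> np.ndarray:
        out = np.full(len(mean_fc), "none", dtype=object)
        out[ctrl_ok & (mean_fc < 1.0 / fold)] = "down"
        out[treat_ok & (mean_fc > fold)] = "up"
        return out

    df = pd.DataFrame(
        {
            **{
                f"fc_{i + 1}": fcs[:, i] for i in range(fcs.shape[1])
            },
            "mean_fc": mean_fc,
            "sd_fc": sd_fc,
            "status_fold2": status(params.up_fold),
            "status_fold1_5": status(params.alt_fold),
        },
        index=norm.index,
    )
    return df


def call_methylated(
    norm_ip: pd.DataFrame,
    norm_ctrl: pd.DataFrame,
    params: RipParams = RipParams(),
) -> pd.DataFrame:
    """Methylation calls from paired anti-m6A IP vs IgG control replicates.

    ``norm_ip`` and ``norm_ctrl`` must hold the same references and the same
    number of replicate columns, paired by position.  Per-replicate enrichment
    is (IP + pc)/(IgG + pc); a reference is called methylated when every IP
    replicate has >= ``min_rpm`` RPM and the mean enrichment is at least
    ``min_fold``.  Output is sorted by mean enrichment, descending.
    """
    if norm_ip.shape[1] != norm_ctrl.shape[1]:
        raise ValueError("unpaired replicates: IP and control column counts differ")
    if not norm_ip.index.equals(norm_ctrl.index):
        raise ValueError("IP and control matrices index different references")
    ip = norm_ip.to_numpy(dtype=float)
    ctrl = norm_ctrl.to_numpy(dtype=float)
    enr = (ip + params.pseudocount) / (ctrl + params.pseudocount)
    mean_enr = enr.mean(axis=1)
    sd_enr = enr.std(axis=1, ddof=1) if enr.shape[1] > 1 else np.zeros(len(enr))
    meth = (ip >= params.min_rpm).all(axis=1) & (mean_enr >= params.min_fold)
    df = pd.DataFrame(
        {
            **{f"enrichment_{i + 1}": enr[:, i] for i in range(enr.shape[1])},
            "mean_enrichment": mean_enr,
            "sd_enrichment": sd_enr,
            "methylated": meth,
        },
        index=norm_ip.index,
    )
    return df.sort_values("mean_enrichment", ascending=False)


def log2_fold_changes(
    enrichment: pd.DataFrame, differential: pd.DataFrame
) -> pd.DataFrame:
    """Joined per-reference (log2 enrichment, log2 knockdown fold change).

    References must appear in both tables; rows with a non-positive mean in
    either analysis are excluded (and logged), since their log2 is undefined.
    """
    common = enrichment.index.intersection(differential.index)
    enr = enrichment.loc[common, "mean_enrichment"]
    fc = differential.loc[common, "mean_fc"]
    ok = (enr > 0) & (fc > 0)
    dropped = list(common[~ok])
    if dropped:
        logger.warning("excluding %d references with zero means: %s",
                       len(dropped), dropped[:10])
    return pd.DataFrame(
        {
            "log2_enrichment": np.log2(enr[ok]),
            "log2_kd_fc": np.log2(fc[ok]),
        }
    )
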