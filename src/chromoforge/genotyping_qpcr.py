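"""PCR-tag genotype calling and efficiency-corrected relative expression.

A megachunk integration is accepted when every informative synthetic tag
amplifies and no informative wild-type tag does; tags whose no-template or
wrong-template control amplifies are excluded as aberrant before any
evidence is counted.  Relative expression uses the efficiency-corrected
(modified-Livak/Pfaffl) ratio, with per-primer-pair amplification
efficiencies rather than an assumed doubling per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("well", "sample", "tag_id", "allele", "Cq", "melt_c", "is_ntc")


class ControlError(ValueError):
    """Required control samples are missing from the plate."""


@dataclass
class CallThresholds:
    cq_max: float = 35.0
    melt_tolerance: float = 1.0  # degrees C


@dataclass
class QpcrTable:
    """Well-level qPCR results plus control-sample labels and expected melts.

    ``data`` columns: well, sample, tag_id, allele (SYN/WT), Cq (NaN = no
    amplification), melt_c, is_ntc.  ``manifest`` columns: tag_id,
    megachunk, melt_syn, melt_wt.
    """

    data: pd.DataFrame
    manifest: pd.DataFrame
    positive_control: str = "POS_CTRL"
    negative_control: str = "NEG_CTRL"

    def __post_init__(self) -> None:
        missing = set(REQUIRED_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns {sorted(missing)}")
        dup = (
            self.data[~self.data["is_ntc"]]
            .groupby(["sample", "tag_id", "allele"])["well"]
            .count()
        )
        self._replicated = bool((dup > 1).any())

    @classmethod
    def from_csv(cls, plate_csv, manifest_tsv, **kw) -> "QpcrTable":
        data = pd.read_csv(plate_csv)
        manifest = pd.read_csv(manifest_tsv, sep=None, engine="python")
        return cls(data=data, manifest=manifest, **kw)


def _amplified(rows: pd.DataFrame, expected_melt: float, th: CallThresholds) -> bool | None:
    """Majority call over replicate wells; ties -> None (aberrant)."""
    votes = []
    for r in rows.itertuples():
        ok = (
            np.isfinite(r.Cq)
            and r.Cq <= th.cq_max
            and np.isfinite(r.melt_c)
            and abs(r.melt_c - expected_melt) <= th.melt_tolerance
        )
        votes.append(bool(ok))
    if not votes:
        return None
    n_pos = sum(votes)
    if 2 * n_pos == len(votes):
        return None
    return 2 * n_pos > len(votes)


def call_tag_presence(
    table: QpcrTable,
    thresholds: CallThresholds | None = None,
    sample: str | None = None,
) -> pd.DataFrame:
    """Per-tag, per-allele presence calls for one test sample.

    Returns columns (tag_id, allele, megachunk, call) with call in
    {amplified, not_amplified, aberrant_excluded}.  A tag/allele is
    aberrant_excluded when its NTC amplifies, when its wrong-template
    control amplifies (negative control for SYN, positive control for WT),
    or when replicate wells tie.
    """
    th = thresholds or CallThresholds()
    df = table.data
    samples = set(df.loc[~df["is_ntc"], "sample"])
    if table.positive_control not in samples or table.negative_control not in samples:
        raise ControlError(
            f"plate must include {table.positive_control} and {table.negative_control}"
        )
    if sample is None:
        test_samples = samples - {table.positive_control, table.negative_control}
        if len(test_samples) != 1:
            raise ValueError(f"ambiguous test sample; specify one of {sorted(test_samples)}")
        sample = test_samples.pop()

    melt = {
        (r.tag_id, "SYN"): r.melt_syn for r in table.manifest.itertuples()
    } | {(r.tag_id, "WT"): r.melt_wt for r in table.manifest.itertuples()}
    mega = {r.tag_id: r.megachunk for r in table.manifest.itertuples()}

    out = []
    for (tag, allele), grp in df.groupby(["tag_id", "allele"]):
        expected = melt.get((tag, allele))
        if expected is None:
            continue
        ntc = grp[grp["is_ntc"]]
        wrong_ctrl = table.negative_control if allele == "SYN" else table.positive_control
        ntc_amp = _amplified(ntc, expected, th) if len(ntc) else False
        wrong = grp[(grp["sample"] == wrong_ctrl) & (~grp["is_ntc"])]
        wrong_amp = _amplified(wrong, expected, th) if len(wrong) else False
        test = grp[(grp["sample"] == sample) & (~grp["is_ntc"])]
        verdict = _amplified(test, expected, th)
        if ntc_amp or wrong_amp or verdict is None:
            call = "aberrant_excluded"
        else:
            call = "amplified" if verdict else "not_amplified"
        out.append(dict(tag_id=tag, allele=allele, megachunk=mega.get(tag), call=call))
    return pd.DataFrame(out).sort_values(["tag_id", "allele"]).reset_index(drop=True)


def assess_megachunk(calls: pd.DataFrame) -> pd.DataFrame:
    """Apply the integration acceptance rule per megachunk.

    accepted  — every informative SYN tag amplified and no informative WT
                tag amplified;
    rejected  — any informative SYN non-amplification or WT amplification;
    indeterminate — no informative tags survive exclusion.
    """
    rows = []
    for mega, grp in calls.groupby("megachunk"):
        informative = grp[grp["call"] != "aberrant_excluded"]
        syn = informative[informative["allele"] == "SYN"]
        wt = informative[informative["allele"] == "WT"]
        n_syn_amp = int((syn["call"] == "amplified").sum())
        n_wt_amp = int((wt["call"] == "amplified").sum())
        if len(informative) == 0:
            status = "indeterminate"
        elif n_syn_amp == len(syn) and n_wt_amp == 0:
            status = "accepted"
        else:
            status = "rejected"
        rows.append(
            dict(
                megachunk=mega,
                status=status,
                n_informative=len(informative),
                n_excluded=int((grp["call"] == "aberrant_excluded").sum()),
                n_syn_amplified=n_syn_amp,
                n_syn_total=len(syn),
                n_wt_amplified=n_wt_amp,
                n_wt_total=len(wt),
            )
        )
    return pd.DataFrame(rows).sort_values("megachunk").reset_index(drop=True)


def relative_expression(
    e_target: float,
    cq_target_calibrator: float,
    cq_target_test: float,
    e_reference: float,
    cq_reference_calibrator: float,
    cq_reference_test: float,
) -> float:
    """Efficiency-corrected relative expression ratio.

    ratio = E_t^(Cq_t,cal - Cq_t,test) / E_r^(Cq_r,cal - Cq_r,test)

    Efficiencies are per-cycle amplification factors in (1, 2]; with both
    equal to 2 this reduces to the classic 2^-ddCq.
    """
    for e in (e_target, e_reference):
        if not (1.0 < e <= 2.0):
            raise ValueError(f"amplification efficiency {e} outside (1, 2]")
    for cq in (cq_target_calibrator, cq_target_test,
               cq_reference_calibrator, cq_reference_test):
        if not np.isfinite(cq):
            raise ValueError("Cq values must be finite")
    ratio = e_target ** (cq_target_calibrator - cq_target_test) / (
        e_reference ** (cq_reference_calibrator - cq_reference_test)
    )
    assert ratio > 0
    return float(ratio)
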