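"""Raw well records -> 12-feature bioenergetic profile per cell line.

Implements the assay-processing conventions of the mito stress test and
companion plate assays:

* technical replicates farther than two standard deviations from the
  replicate mean are discarded (single pass, sample SD),
* non-mitochondrial oxygen consumption (the antimycin A + rotenone phase)
  is subtracted from all OCR values of the same line,
* FCCP-depolarized background fluorescence is subtracted from total
  TMRM/MTG fluorescence,
* ATP luminescence is converted to ATP amount through the standard curve,
* everything is normalized by the line's mean protein content (per mg).

Flux metrics follow the standard mito-stress-test definitions: baseline
OCR; oligomycin-sensitive OCR (baseline minus post-oligomycin, the
ATP-synthesis-linked respiration); maximal (FCCP-uncoupled) OCR; spare
respiratory capacity (maximal minus baseline); baseline ECAR; ECAR after
AA+Rot (maximal glycolytic acidification); and the OCR/ECAR ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ATP_CONDITIONS,
    DYES,
    FEATURES,
    FLUX_PHASES,
    Cohort,
    validate_profiles,
)

__all__ = [
    "replicate_qc",
    "nonmito_correct",
    "flux_features",
    "tmrm_mtg_features",
    "atp_features",
    "interp_extrap",
    "build_profiles",
    "QcLog",
]


def replicate_qc(values: np.ndarray) -> np.ndarray:
    """Keep-mask for technical replicates: keep iff |x - mean| <= 2 * SD.

    Mean and sample SD (n-1 denominator) are computed once over all
    replicates — a single pass, not iterative. With zero spread every
    value is kept. Requires at least two values (SD undefined below that).

    Note a hard arithmetic bound: since sum((x-mean)^2) = (n-1)*SD^2, at
    most floor((n-1)/4) replicates can exceed 2*SD, so the mask is never
    all-False and triplicates can never lose a member.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("replicate QC requires at least 2 values (SD undefined)")
    sd = values.std(ddof=1)
    if sd == 0:
        return np.ones(values.shape, dtype=bool)
    return np.abs(values - values.mean()) <= 2.0 * sd


def nonmito_correct(phase_ocr: dict[str, float]) -> dict[str, float]:
    """Subtract non-mitochondrial OCR (AA+Rot phase) from every phase.

    ``phase_ocr`` maps phase name -> QC-passed mean OCR. The AA_Rot entry
    becomes 0 by construction. ECAR is never corrected.
    """
    if "AA_Rot" not in phase_ocr:
        raise ValueError("non-mito correction requires a surviving AA_Rot phase")
    floor = phase_ocr["AA_Rot"]
    return {phase: value - floor for phase, value in phase_ocr.items()}


def flux_features(corrected_ocr: dict[str, float], ecar: dict[str, float],
                  protein: float) -> dict[str, float]:
    """Six flux metrics plus the OCR/ECAR ratio, protein-normalized.

    ``corrected_ocr`` holds non-mito-corrected OCR per phase, ``ecar`` raw
    ECAR per phase. The oligomycin-sensitive rate is baseline minus
    oligomycin OCR; the non-mito floor cancels in that difference, so it is
    identical whether computed from corrected or raw rates.
    """
    if protein <= 0:
        raise ValueError("protein must be positive")
    for phase in FLUX_PHASES:
        if phase not in corrected_ocr:
            raise ValueError(f"missing OCR phase '{phase}'")
    ocr_base = corrected_ocr["baseline"] / protein
    ocr_max = corrected_ocr["FCCP"] / protein
    ecar_base = ecar["baseline"] / protein
    out = {
        "ocr_base": ocr_base,
        "ocr_oligo_sens": (corrected_ocr["baseline"] - corrected_ocr["oligomycin"]) / protein,
        "ocr_max": ocr_max,
        "ocr_spare": ocr_max - ocr_base,
        "ecar_base": ecar_base,
        "ecar_aarot": ecar["AA_Rot"] / protein,
        "ocr_ecar_ratio": ocr_base / ecar_base if ecar_base > 0 else np.nan,
    }
    return out


def tmrm_mtg_features(fluor: pd.DataFrame, protein: float) -> tuple[dict[str, float], int]:
    """Background-subtracted TMRM and MTG fluorescence per mg protein.

    Per dye: mean QC-passed untreated RFU minus mean QC-passed
    FCCP-treated (fully depolarized background) RFU, divided by protein.
    A negative difference can only arise from noise, so it is clamped to 0;
    the number of clamps is returned for noise-calibration monitoring.
    """
    if protein <= 0:
        raise ValueError("protein must be positive")
    out: dict[str, float] = {}
    clamped = 0
    for dye, feat in (("TMRM", "tmrm"), ("MTG", "mtg")):
        sub = fluor[fluor["dye"] == dye]
        signal = sub.loc[~sub["fccp_treated"], "rfu"].to_numpy(float)
        background = sub.loc[sub["fccp_treated"], "rfu"].to_numpy(float)
        if signal.size == 0 or background.size == 0:
            raise ValueError(f"missing untreated or FCCP background wells for dye {dye}")
        signal = signal[replicate_qc(signal)] if signal.size >= 2 else signal
        background = background[replicate_qc(background)] if background.size >= 2 else background
        value = (signal.mean() - background.mean()) / protein
        if value < 0:
            value = 0.0
            clamped += 1
        out[feat] = value
    return out, clamped


def interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with end-segment linear extrapolation."""
    x = np.asarray(x, dtype=float)
    xp = np.asarray(xp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if lo.any():
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    if hi.any():
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


def atp_features(atp: pd.DataFrame, standard: pd.DataFrame,
                 protein: float) -> dict[str, float]:
    """ATP content at baseline and its loss after 2DG / oligomycin, per mg.

    Luminescence is converted to ATP amount by linear interpolation on the
    standard curve (end segments extrapolate). Deltas are baseline minus
    treated, so a *rise* in ATP after oligomycin yields a negative
    atp_oligo_delta.
    """
    if protein <= 0:
        raise ValueError("protein must be positive")
    std = standard.sort_values("atp_amount")
    lum = std["luminescence"].to_numpy(float)
    amt = std["atp_amount"].to_numpy(float)
    if len(std) < 2:
        raise ValueError("ATP standard needs at least 2 points")
    if not (np.diff(lum) > 0).all():
        raise ValueError("ATP standard luminescence must be strictly increasing")
    per_condition: dict[str, float] = {}
    for condition in ATP_CONDITIONS:
        wells = atp.loc[atp["condition"] == condition, "luminescence"].to_numpy(float)
        if wells.size == 0:
            raise ValueError(f"missing ATP wells for condition '{condition}'")
        amounts = interp_extrap(wells, lum, amt)
        if amounts.size >= 2:
            amounts = amounts[replicate_qc(amounts)]
        per_condition[condition] = amounts.mean() / protein
    return {
        "atp_base": per_condition["baseline"],
        "atp_2dg_delta": per_condition["baseline"] - per_condition["dg2"],
        "atp_oligo_delta": per_condition["baseline"] - per_condition["oligo"],
    }


@dataclass
class QcLog:
    """Per-line QC outcomes: discarded replicates and failed lines."""

    records: list[dict] = field(default_factory=list)

    def discard(self, line_id: str, stage: str, n: int) -> None:
        if n:
            self.records.append({"line_id": line_id, "stage": stage,
                                 "reason": "replicate outside 2 SD", "n_discarded": n})

    def fail(self, line_id: str, stage: str, reason: str) -> None:
        self.records.append({"line_id": line_id, "stage": stage,
                             "reason": reason, "n_discarded": 0})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records,
                            columns=["line_id", "stage", "reason", "n_discarded"])


def _line_protein(*tables: pd.DataFrame) -> float:
    vals = np.concatenate([t["protein"].dropna().to_numpy(float) for t in tables if len(t)])
    return float(vals.mean()) if vals.size else np.nan


def _flux_line(flux: pd.DataFrame, line_id: str, log: QcLog) -> dict[str, float] | None:
    # average cycles within each well/phase first: one rate per well per phase
    per_well = (flux.groupby(["well_id", "phase"], sort=False)[["ocr_raw", "ecar_raw"]]
                .mean().reset_index())
    ocr_mean: dict[str, float] = {}
    ecar_mean: dict[str, float] = {}
    for phase in FLUX_PHASES:
        sub = per_well[per_well["phase"] == phase]
        if len(sub) < 2:
            log.fail(line_id, "flux", f"fewer than 2 wells in phase '{phase}'")
            return None
        for signal, target in (("ocr_raw", ocr_mean), ("ecar_raw", ecar_mean)):
            vals = sub[signal].to_numpy(float)
            keep = replicate_qc(vals)
            log.discard(line_id, f"flux/{signal[:-4]}/{phase}", int((~keep).sum()))
            if keep.sum() < 2:
                log.fail(line_id, "flux", f"fewer than 2 wells survive QC in '{phase}'")
                return None
            target[phase] = float(vals[keep].mean())
    protein = _line_protein(flux)
    if not np.isfinite(protein) or protein <= 0:
        log.fail(line_id, "flux", "missing or non-positive protein")
        return None
    corrected = nonmito_correct(ocr_mean)
    return flux_features(corrected, ecar_mean, protein)


def build_profiles(cohort: Cohort) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full extraction for every line of a cohort.

    Returns ``(profiles, qc_report)``. A line appears in ``profiles`` with
    whichever features its assays support (missing assay family -> NaN for
    those features); lines whose assay fails a QC precondition are listed
    in the report with the failing stage. Deterministic given the input.
    """
    log = QcLog()
    flux_by_line = dict(tuple(cohort.flux.groupby("line_id", sort=False)))
    fluor_by_line = dict(tuple(cohort.fluorescence.groupby("line_id", sort=False)))
    atp_by_line = dict(tuple(cohort.atp.groupby("line_id", sort=False)))

    rows = []
    for line_id in cohort.lines["line_id"]:
        row: dict[str, float | str] = {"line_id": line_id}
        row.update({feat: np.nan for feat in FEATURES})

        flux = flux_by_line.get(line_id)
        if flux is not None and len(flux):
            feats = _flux_line(flux, line_id, log)
            if feats is not None:
                row.update(feats)

        fluor = fluor_by_line.get(line_id)
        if fluor is not None and len(fluor):
            protein = _line_protein(fluor)
            try:
                feats, n_clamped = tmrm_mtg_features(fluor, protein)
                row.update(feats)
                if n_clamped:
                    log.fail(line_id, "fluorescence",
                             f"{n_clamped} negative background-subtracted value(s) clamped to 0")
            except ValueError as exc:
                log.fail(line_id, "fluorescence", str(exc))

        atp = atp_by_line.get(line_id)
        if atp is not None and len(atp):
            protein = _line_protein(atp)
            try:
                row.update(atp_features(atp, cohort.atp_standard, protein))
            except ValueError as exc:
                log.fail(line_id, "atp", str(exc))

        rows.append(row)

    profiles = pd.DataFrame(rows, columns=["line_id", *FEATURES])
    complete = profiles.dropna()
    if len(complete):
        validate_profiles(complete)
    return profiles, log.to_frame()
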