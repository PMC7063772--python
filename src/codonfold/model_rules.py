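"""Formal profile-model classification.

Two nested models describe the canonical ΔLFE profile shape:

* **Model 1 (positive ends)** — A: ΔLFE positive and significant at
  start offsets 0–10 nt; B: a transition peak (profile minimum) at
  20–80 nt, significantly below both flanks; C: ΔLFE negative and
  significant at every offset 200–300 nt from both the start and the
  end; D: positive and significant at end offsets 10–0 nt; E = A∧C∧D.
* **Model 2 (weak ends)** — as Model 1 but A/D only require the
  terminal position to be significantly *higher* than each mid-CDS
  position (paired test), not positive in absolute terms.

Significance for positional rules is the position Wilcoxon (p < 0.05
at every offset in the stated range).  Comparisons between two
positions use paired differences w_i(p, n) = d_ref(p, n) - d_i(p, n)
over the (CDS, replicate) pairs covering both offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dlfe import DLFEResult, position_wilcoxon

__all__ = ["ModelClassification", "classify_model1", "classify_model2",
           "detect_transition_peak", "paired_position_test"]

ALPHA = 0.05
START_RANGE = (0, 10)
MID_RANGE = tuple(range(200, 301, 10))
PEAK_SEARCH = (20, 80)
PEAK_FLANKS = (0, 10) + tuple(range(100, 201, 10))


@dataclass
class ModelClassification:
    model: str  # 'model1' or 'model2'
    elements: dict[str, bool]
    peak_position: int | None = None
    detail: dict = field(default_factory=dict)

    @property
    def conforms(self) -> bool:
        """Model structure element E = A and C and D."""
        return self.elements["E_structure"]


def _require_offsets(result: DLFEResult, offsets, what: str) -> None:
    missing = [o for o in offsets
               if o not in result.positions or
               result.n_cds_per_position[np.where(result.positions == o)[0][0]] == 0]
    if missing:
        raise ValueError(f"{what}: profile lacks data at offsets {missing}")


def _at(result: DLFEResult, offset: int) -> tuple[float, float]:
    j = np.where(result.positions == offset)[0][0]
    return float(result.mean_dlfe[j]), float(result.p_values[j])


def paired_position_test(result: DLFEResult, ref_offset: int, cmp_offset: int
                         ) -> tuple[float, float, int]:
    """Paired Wilcoxon between two window offsets of one profile.

    Returns (two-sided p, median w, n pairs) for w(p, n) =
    d_ref(p, n) - d_cmp(p, n), restricted to CDSs covering both
    offsets.  No overlapping CDS -> (nan, nan, 0).
    """
    chunks = []
    for offs, d in result.diffs_store.values():
        ir = np.where(offs == ref_offset)[0]
        ic = np.where(offs == cmp_offset)[0]
        if len(ir) and len(ic):
            chunks.append(d[:, ir[0]] - d[:, ic[0]])
    if not chunks:
        return float("nan"), float("nan"), 0
    w = np.concatenate(chunks)
    return position_wilcoxon(w), float(np.median(w)), len(w)


def _positionwise_positive(result: DLFEResult, offsets) -> tuple[bool, dict]:
    detail = {}
    ok = True
    for off in offsets:
        mean, p = _at(result, off)
        detail[off] = (mean, p)
        ok = ok and (mean > 0) and (p < ALPHA)
    return ok, detail


def _positionwise_negative(result: DLFEResult, offsets) -> tuple[bool, dict]:
    detail = {}
    ok = True
    for off in offsets:
        mean, p = _at(result, off)
        detail[off] = (mean, p)
        ok = ok and (mean < 0) and (p < ALPHA)
    return ok, detail


def _mid_element(start: DLFEResult, end: DLFEResult) -> tuple[bool, dict]:
    """Element C: negative and significant at 200-300 nt from both ends."""
    ok_s, det_s = _positionwise_negative(start, MID_RANGE)
    ok_e, det_e = _positionwise_negative(end, MID_RANGE)
    return ok_s and ok_e, {"start": det_s, "end": det_e}


def detect_transition_peak(result_start: DLFEResult,
                           alpha: float = ALPHA) -> tuple[bool, int | None, dict]:
    """Element B: localized profile minimum 20-80 nt after the start.

    i* is the argmin of the mean ΔLFE over offsets 0-300.  B holds iff
    i* lies in 20-80 nt and the peak is significantly lower than every
    flank offset in {0, 10} ∪ {100..200}: paired Wilcoxon on
    w_i(p, n) = d_i*(p, n) - d_i(p, n) with p < alpha and median w < 0
    (peak below the flank).
    """
    means = result_start.mean_dlfe
    if np.all(np.isnan(means)):
        return False, None, {"reason": "empty profile"}
    i_star = int(result_start.positions[int(np.nanargmin(means))])
    detail: dict = {"i_star": i_star, "flanks": {}}
    if not (PEAK_SEARCH[0] <= i_star <= PEAK_SEARCH[1]):
        detail["reason"] = "argmin outside 20-80 nt"
        return False, i_star, detail
    ok = True
    for off in PEAK_FLANKS:
        p, med, n = paired_position_test(result_start, i_star, off)
        detail["flanks"][off] = (p, med, n)
        if n == 0 or np.isnan(p) or not (p < alpha and med < 0):
            ok = False
    return ok, i_star, detail


def classify_model1(result_start: DLFEResult, result_end: DLFEResult
                    ) -> ModelClassification:
    """Model 1 (positive ends) element evaluation."""
    _require_offsets(result_start, START_RANGE + MID_RANGE, "model1/start")
    _require_offsets(result_end, START_RANGE + MID_RANGE, "model1/end")
    a, det_a = _positionwise_positive(result_start, START_RANGE)
    b, i_star, det_b = detect_transition_peak(result_start)
    c, det_c = _mid_element(result_start, result_end)
    d, det_d = _positionwise_positive(result_end, START_RANGE)
    elements = {"A_start": a, "B_peak": b, "C_mid": c, "D_end": d,
                "E_structure": a and c and d}
    return ModelClassification("model1", elements, i_star,
                               {"A": det_a, "B": det_b, "C": det_c, "D": det_d})


def _weak_end_element(result: DLFEResult, alpha: float = ALPHA) -> tuple[bool, dict]:
    """Offset 0 significantly higher than each offset in 200-300 nt."""
    detail = {}
    ok = True
    for off in MID_RANGE:
        p, med, n = paired_position_test(result, 0, off)
        detail[off] = (p, med, n)
        if n == 0 or np.isnan(p) or not (p < alpha and med > 0):
            ok = False
    return ok, detail


def classify_model2(result_start: DLFEResult, result_end: DLFEResult
                    ) -> ModelClassification:
    """Model 2 (weak ends): terminal positions higher than mid-CDS.

    Model 2 relaxes Model 1's A/D: the profile need not be positive at
    the termini, only significantly higher there than at 200-300 nt
    (paired test, same w-construction as the peak rule); C and B are
    unchanged.  Model 1 conformance implies Model 2 conformance.
    """
    _require_offsets(result_start, (0,) + MID_RANGE, "model2/start")
    _require_offsets(result_end, (0,) + MID_RANGE, "model2/end")
    a, det_a = _weak_end_element(result_start)
    b, i_star, det_b = detect_transition_peak(result_start)
    c, det_c = _mid_element(result_start, result_end)
    d, det_d = _weak_end_element(result_end)
    elements = {"A_start": a, "B_peak": b, "C_mid": c, "D_end": d,
                "E_structure": a and c and d}
    return ModelClassification("model2", elements, i_star,
                               {"A": det_a, "B": det_b, "C": det_c, "D": det_d})
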