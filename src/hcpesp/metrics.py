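"""Accuracy and work metrics comparing evaluation modes.

The central accuracy measure is the relative root-mean-squared error,

    relative RMSE = RMS(test - reference) / RMS(reference),

a scale-invariant summary of the elementwise deviation between two
per-vertex potential sets.  Work is compared through kernel-call counts
(single-charge evaluations), the platform-neutral analogue of runtime.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alpb_kernel import ALPBParams
from .esp_engines import ESPResult, HCPThresholds, esp_exact, esp_hcp
from .hierarchy import Structure
from .io_structs import VertexSet


@dataclasses.dataclass
class ComparisonReport:
    """Accuracy and work of a test mode against a reference mode.

    ``work_ratio`` is kernel_calls_b / kernel_calls_a, i.e. test work over
    reference work; values < 1 mean the test mode does less work.
    """

    relative_rmse: float
    max_abs_diff: float
    kernel_calls_a: int
    kernel_calls_b: int
    work_ratio: float
    level_usage: dict[str, int] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "relative_rmse": self.relative_rmse,
            "max_abs_diff": self.max_abs_diff,
            "kernel_calls_a": self.kernel_calls_a,
            "kernel_calls_b": self.kernel_calls_b,
            "work_ratio": self.work_ratio,
            "level_usage": dict(self.level_usage),
        }


def relative_rmse(test, reference) -> float:
    """RMS of the elementwise error over RMS of the reference.

    Scale-invariant (both arrays scaled by the same nonzero constant leave
    the value unchanged) and zero iff the arrays are equal.

    Raises
    ------
    ValueError
        On length mismatch, empty input, or identically-zero reference.
    """
    t = np.asarray(test, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if t.shape != ref.shape or t.size == 0:
        raise ValueError(f"arrays must share a non-empty shape, got {t.shape} vs {ref.shape}")
    ref_rms = np.sqrt(np.mean(ref**2))
    if ref_rms == 0:
        raise ValueError("reference is identically zero; relative RMSE undefined")
    return float(np.sqrt(np.mean((t - ref) ** 2)) / ref_rms)


def _report(test: ESPResult, reference: ESPResult) -> ComparisonReport:
    return ComparisonReport(
        relative_rmse=relative_rmse(test.potentials, reference.potentials),
        max_abs_diff=float(np.max(np.abs(test.potentials - reference.potentials))),
        kernel_calls_a=reference.kernel_calls,
        kernel_calls_b=test.kernel_calls,
        work_ratio=test.kernel_calls / reference.kernel_calls,
        level_usage=dict(test.level_usage),
    )


def compare_modes(
    structure: Structure,
    vertices: VertexSet,
    params: ALPBParams | None = None,
    thresholds: HCPThresholds | None = None,
    order: int = 2,
) -> ComparisonReport:
    """HCP (test) against the exact all-atom engine (reference)."""
    params = params or ALPBParams()
    thresholds = thresholds or HCPThresholds()
    reference = esp_exact(structure, vertices, params)
    test = esp_hcp(structure, vertices, params, thresholds, order=order)
    return _report(test, reference)


def precision_study(
    structure: Structure,
    vertices: VertexSet,
    params: ALPBParams | None = None,
    thresholds: HCPThresholds | None = None,
    mode: str = "exact",
    order: int = 2,
    test_precision: str = "single",
    reference_precision: str = "double",
) -> ComparisonReport:
    """Reduced- vs full-precision evaluation of the same traversal.

    Both runs use the same mode and thresholds; in HCP mode the distance
    tests are always double precision, so the two runs visit identical
    charge sets and the report isolates pure rounding error from
    approximation-path divergence.
    """
    params = params or ALPBParams()
    thresholds = thresholds or HCPThresholds()

    def run(precision: str) -> ESPResult:
        if mode == "exact":
            return esp_exact(structure, vertices, params, precision=precision)
        if mode == "hcp":
            return esp_hcp(structure, vertices, params, thresholds, order=order, precision=precision)
        raise ValueError(f"mode must be 'exact' or 'hcp', got {mode!r}")

    return _report(run(test_precision), run(reference_precision))


def threshold_sweep(
    structure: Structure,
    vertices: VertexSet,
    params: ALPBParams | None = None,
    threshold_grid: list[tuple[float, float]] | None = None,
    order: int = 2,
):
    """Accuracy/work trade-off over a grid of (h_residue, h_strand) pairs.

    The exact reference is computed once.  Returns a pandas DataFrame with
    columns ``h_residue, h_strand, relative_rmse, kernel_calls``.
    """
    import pandas as pd

    if not threshold_grid:
        raise ValueError("threshold_grid must be non-empty")
    params = params or ALPBParams()
    reference = esp_exact(structure, vertices, params)
    rows = []
    for h_res, h_str in threshold_grid:
        result = esp_hcp(
            structure, vertices, params, HCPThresholds(residue=h_res, strand=h_str), order=order
        )
        rows.append(
            {
                "h_residue": h_res,
                "h_strand": h_str,
                "relative_rmse": relative_rmse(result.potentials, reference.potentials),
                "kernel_calls": result.kernel_calls,
            }
        )
    return pd.DataFrame(rows)
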