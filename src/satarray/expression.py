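"""Expression quantification utilities: TPM and -ddCt fold change."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .errors import DataError


def tpm_normalize(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """Transcripts per million.

    ``rate_i = count_i / length_i``; ``TPM_i = 1e6 * rate_i / sum(rates)``.
    TPM values sum to 1e6 by construction.
    """
    counts = np.asarray(counts, dtype=np.float64)
    lengths = np.asarray(lengths, dtype=np.float64)
    if counts.shape != lengths.shape:
        raise DataError("counts and lengths must have the same shape")
    if np.any(lengths <= 0):
        raise DataError("all lengths must be > 0")
    if np.any(counts < 0):
        raise DataError("counts must be non-negative")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        raise DataError("all counts are zero; TPM undefined")
    return 1e6 * rates / total


def ddct_fold_change(ct_target_treated: float, ct_ref_treated: float,
                     ct_target_control: float, ct_ref_control: float) -> float:
    """Fold change by the -ddCt method.

    ``dCt = Ct_target - Ct_reference`` per condition;
    ``ddCt = dCt_treated - dCt_control``; fold change ``= 2 ** (-ddCt)``.
    A reference gene (e.g. a housekeeping transcript) normalizes for input
    amount; the control condition anchors the comparison at fold 1.
    """
    values = (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)
    if not all(np.isfinite(v) for v in values):
        raise DataError("all Ct values must be finite")
    dct_treated = ct_target_treated - ct_ref_treated
    dct_control = ct_target_control - ct_ref_control
    return float(2.0 ** (-(dct_treated - dct_control)))
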