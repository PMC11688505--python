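"""Mean glandular dose from user-supplied spectral tables.

MGD = sum over energy bins E of DgN(E) * K(E) * kappa, with DgN(E) the
monoenergetic normalized glandular dose coefficient (mGy per R), K(E) the
measured air kerma per bin (R) and kappa the roentgen-to-mGy conversion
factor (default 0.114 R/mGy).  The kerma is a measured quantity — this
module only performs the spectral sum; no DgN tabulations ship with the
package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DgNTable", "mean_glandular_dose", "KAPPA_DEFAULT"]

KAPPA_DEFAULT = 0.114  # R/mGy


@dataclass
class DgNTable:
    energies: np.ndarray  # keV bin centres
    dgn: np.ndarray       # DgN(E), mGy/R
    kerma: np.ndarray     # K(E), R
    kappa: float = KAPPA_DEFAULT

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.dgn = np.asarray(self.dgn, dtype=np.float64)
        self.kerma = np.asarray(self.kerma, dtype=np.float64)
        if not (self.energies.shape == self.dgn.shape == self.kerma.shape):
            raise ValueError("energies, dgn and kerma must have equal lengths")
        if self.energies.ndim != 1:
            raise ValueError("table columns must be 1D")
        if np.any(self.dgn < 0) or np.any(self.kerma < 0) or self.kappa < 0:
            raise ValueError("table entries must be non-negative")


def mean_glandular_dose(table: DgNTable) -> float:
    """Spectrally summed mean glandular dose in mGy."""
    if table.energies.size == 0:
        raise ValueError("empty DgN table")
    return float(np.sum(table.dgn * table.kerma * table.kappa))
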