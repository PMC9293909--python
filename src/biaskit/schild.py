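"""Single-dose Schild analysis.

A competitive antagonist at fixed concentration [A] shifts an agonist's
EC50 from D to D' according to

    D'/D = 1 + [A] * K_2

where K_2 is the antagonist's affinity constant (per molar).  The
dissociation constant is K_d = 1/K_2 and pK_d = -log10(K_d in M); a dose
ratio of 2 therefore pins [A] = K_d.  One observed shift at one antagonist
concentration suffices — the "single-dose" form — and multiple antagonist
concentrations are summarised as the unweighted mean pK_d +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from biaskit.assay_core import AssayError
from biaskit.dose_response import LogisticFit

__all__ = [
    "NoShiftError",
    "SchildResult",
    "single_dose_schild",
    "schild_from_fits",
    "summarize_schild",
]


class NoShiftError(AssayError):
    """The antagonist produced no rightward EC50 shift (dose ratio <= 1)."""


@dataclass
class SchildResult:
    """Antagonist affinity from one agonist-curve shift."""

    agonist_id: str
    antagonist_id: str
    d: float  # agonist EC50 without antagonist (M)
    d_prime: float  # agonist EC50 with antagonist (M)
    antagonist_conc: float  # [A] in M
    pkd_decimals: int = 1

    @property
    def dose_ratio(self) -> float:
        return self.d_prime / self.d

    @property
    def k2(self) -> float:
        """Affinity constant, per molar."""
        return (self.dose_ratio - 1.0) / self.antagonist_conc

    @property
    def kd(self) -> float:
        return 1.0 / self.k2

    @property
    def pkd(self) -> float:
        """-log10(K_d), rounded to the configured number of decimals."""
        return round(-np.log10(self.kd), self.pkd_decimals)

    def to_record(self) -> dict:
        return {
            "agonist": self.agonist_id,
            "antagonist": self.antagonist_id,
            "d_M": self.d,
            "d_prime_M": self.d_prime,
            "antagonist_conc_M": self.antagonist_conc,
            "dose_ratio": self.dose_ratio,
            "k2_per_M": self.k2,
            "kd_M": self.kd,
            "pkd": self.pkd,
        }


def single_dose_schild(
    d: float,
    d_prime: float,
    antagonist_conc: float,
    agonist_id: str = "agonist",
    antagonist_id: str = "antagonist",
    pkd_decimals: int = 1,
) -> SchildResult:
    """Antagonist affinity from one EC50 shift: K_2 = (D'/D - 1)/[A]."""
    if not (d > 0 and d_prime > 0 and antagonist_conc > 0):
        raise ValueError("D, D' and [A] must all be positive")
    if d_prime / d <= 1.0:
        raise NoShiftError(
            f"dose ratio D'/D = {d_prime / d:.3g} <= 1: no antagonism detected"
        )
    return SchildResult(
        agonist_id=agonist_id,
        antagonist_id=antagonist_id,
        d=float(d),
        d_prime=float(d_prime),
        antagonist_conc=float(antagonist_conc),
        pkd_decimals=pkd_decimals,
    )


def schild_from_fits(
    fit_ctrl: LogisticFit,
    fit_antag: LogisticFit,
    antagonist_conc: float,
    antagonist_id: str = "antagonist",
    pkd_decimals: int = 1,
) -> SchildResult:
    """Schild analysis over fitted agonist curves with/without antagonist.

    D and D' are recovered from the fits as 10^(-p_half); both fits must
    be non-NR and describe the same agonist/pathway.
    """
    if fit_ctrl.nr_flag or fit_antag.nr_flag:
        raise AssayError("cannot run Schild analysis on an NR fit")
    if (fit_ctrl.ligand_id, fit_ctrl.pathway_id) != (fit_antag.ligand_id, fit_antag.pathway_id):
        raise AssayError("control and antagonist fits must share agonist and pathway")
    return single_dose_schild(
        d=10.0 ** (-fit_ctrl.p_half),
        d_prime=10.0 ** (-fit_antag.p_half),
        antagonist_conc=antagonist_conc,
        agonist_id=fit_ctrl.ligand_id,
        antagonist_id=antagonist_id,
        pkd_decimals=pkd_decimals,
    )


def summarize_schild(results: list[SchildResult]) -> dict:
    """Unweighted mean pK_d +/- SEM over several antagonist concentrations."""
    if not results:
        raise AssayError("no Schild results to summarise")
    pkds = np.array([-np.log10(r.kd) for r in results])
    sem = float(np.std(pkds, ddof=1) / np.sqrt(pkds.size)) if pkds.size > 1 else float("nan")
    return {
        "antagonist": results[0].antagonist_id,
        "n": int(pkds.size),
        "mean_pkd": float(np.mean(pkds)),
        "sem_pkd": sem,
    }
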