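"""Bundled reference data tables."""

from importlib import resources

import pandas as pd

__all__ = ["load_reference_cohort", "PARAM_COLUMNS"]

#: Canonical column order of a per-subject parameter table.
PARAM_COLUMNS = ["G_max", "c", "BP_ctr", "k", "mu", "P", "dG", "c_tilde"]


def load_reference_cohort() -> pd.DataFrame:
    """Best-fitting cochlear model parameters for a published reference
    cohort of 12 normal-hearing listeners (2-kHz signal, contralateral
    54-dB SPL broadband-noise elicitor).

    Columns: ``subject_id`` plus :data:`PARAM_COLUMNS` — maximum gain
    ``G_max`` (dB), compression exponent ``c``, center of the compressive
    range ``BP_ctr`` (dB SPL), threshold signal-to-masker ratio ``k``,
    masker-effect decay rate ``mu`` (dB/ms), passive tail attenuation ``P``
    (dB), elicitor-induced gain reduction ``dG`` (dB), and with-elicitor
    compression exponent ``c_tilde``.
    """
    with resources.files("mocgain.data").joinpath(
        "reference_cohort.csv"
    ).open() as fh:
        return pd.read_csv(fh)
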