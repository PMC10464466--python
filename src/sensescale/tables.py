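"""Published standardized loading matrices for the three sensory response patterns.

These are the fully standardized general + specific loadings reported for
the final confirmatory bifactor graded-response models of caregiver-reported
sensory hyperreactivity (HYPER, 23 items, 6 modality-specific factors),
hyporeactivity (HYPO, 12 items, 3 specific factors plus 4 general-only
single indicators), and sensory seeking (SEEK, revised 18-item model,
4 specific factors). They serve as worked-example inputs for the bifactor
index suite and as generating parameters for synthetic data.
"""

from importlib import resources

import pandas as pd

from .indices import LoadingMatrix

__all__ = ["published_loadings", "PATTERNS"]

PATTERNS = ("HYPER", "HYPO", "SEEK")

_FILES = {
    "HYPER": "hyper_loadings.csv",
    "HYPO": "hypo_loadings.csv",
    "SEEK": "seek_loadings.csv",
}


def published_loadings(pattern: str) -> LoadingMatrix:
    """Return the published standardized loading matrix for a response pattern.

    Parameters
    ----------
    pattern : {"HYPER", "HYPO", "SEEK"}
    """
    key = pattern.upper()
    if key not in _FILES:
        raise KeyError(f"unknown response pattern {pattern!r}; expected one of {PATTERNS}")
    with resources.files("sensescale.data").joinpath(_FILES[key]).open() as fh:
        df = pd.read_csv(fh)
    return LoadingMatrix.from_frame(df)
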