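"""Packaged study tables.

The nine-study characteristics table of the hepatocellular-carcinoma
marker meta-analysis ships with the package as a CSV fixture (identifiers,
arm sizes, assay, follow-up and reported endpoints only — per-study hazard
ratios and 2x2 tables were published as figures/supplements and are not
transcribed here). One study reports no survival data and is excluded from
survival pooling; quality (NOS) scores were not published per study and are
left missing.
"""

from importlib import resources
from typing import List

from .records import StudyRecord
from .study_io import load_studies


def included_studies() -> List[StudyRecord]:
    """The nine source studies (1435 patients) as validated records."""
    ref = resources.files("hccmeta") / "data" / "included_studies.csv"
    with resources.as_file(ref) as path:
        return load_studies(path, format="csv")
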