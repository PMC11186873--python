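"""Packaged cohort tables: molecular features of the three study cohorts.

Two CSV transcriptions ship with the package: the 27-individual PHIP
(Chung-Jansen) cohort (13 training + 14 validation samples) and the
32-individual PHF6/DDB1 table (24 BFLS + 8 WHIKERS records, each split
into discovery and testing roles). They are metadata only — variant
descriptions, ACMG-style classes, sex and cohort roles — and are
validated against a checksum and expected record counts at load time.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import FixtureCorruptionError

VARIANT_TYPES = {"FS", "Mis", "NS", "SL", "Splice"}

_CHECKSUMS = {
    "chujans_cohort.csv": "81a499463519fa1c3481420f3fe0f5eabe28107b0669800a28c3aabdcea848bf",
    "bfls_whikers_cohort.csv": "e795c738e776df4018cda75aeb95c36e94f21c8bf2ae395674ea7185562d0c9e",
}


@dataclass
class CohortFixture:
    """Validated fixture tables for the three study cohorts."""

    chujans: pd.DataFrame  # 27 PHIP records
    bfls_whikers: pd.DataFrame  # 24 PHF6 + 8 DDB1 records

    @property
    def bfls(self) -> pd.DataFrame:
        return self.bfls_whikers[self.bfls_whikers["gene"] == "PHF6"]

    @property
    def whikers(self) -> pd.DataFrame:
        return self.bfls_whikers[self.bfls_whikers["gene"] == "DDB1"]


def _read_checked(name: str) -> pd.DataFrame:
    ref = resources.files("episig.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureCorruptionError(
            f"checksum mismatch for packaged fixture {name!r}: {digest}"
        )
    with ref.open("r") as handle:
        return pd.read_csv(handle)


def load_fixture_tables() -> CohortFixture:
    """Load and validate the packaged cohort tables.

    Raises :class:`FixtureCorruptionError` on checksum mismatch or when
    record counts / vocabularies do not match the expected structure.
    """
    chujans = _read_checked("chujans_cohort.csv")
    bfls_whikers = _read_checked("bfls_whikers_cohort.csv")
    problems = []
    if len(chujans) != 27:
        problems.append(f"PHIP table has {len(chujans)} records, expected 27")
    if len(bfls_whikers) != 32:
        problems.append(f"PHF6/DDB1 table has {len(bfls_whikers)} records, expected 32")
    if (bfls_whikers["gene"] == "PHF6").sum() != 24:
        problems.append("expected 24 PHF6 records")
    if (bfls_whikers["gene"] == "DDB1").sum() != 8:
        problems.append("expected 8 DDB1 records")
    for table, label in ((chujans, "PHIP"), (bfls_whikers, "PHF6/DDB1")):
        bad = set(table["variant_type"]) - VARIANT_TYPES
        if bad:
            problems.append(f"{label} table has unknown variant types: {sorted(bad)}")
        bad_sex = set(table["sex"]) - {"M", "F"}
        if bad_sex:
            problems.append(f"{label} table has unknown sex values: {sorted(bad_sex)}")
    if problems:
        raise FixtureCorruptionError("; ".join(problems))
    return CohortFixture(chujans=chujans, bfls_whikers=bfls_whikers)
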