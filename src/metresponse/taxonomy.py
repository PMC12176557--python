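"""Anatomical site taxonomy for multi-site metastatic ovarian cancer.

Metastatic lesions are labelled with a fixed numerical code system by
anatomical location. The 15 codes are grouped into three regions:
peritoneal sites, lymph nodes, and other (thoracic) sites. The taxonomy is
shipped with the package as a JSON resource and is immutable at run time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

REGIONS = ("peritoneal", "lymph_node", "other")

#: Canonical timepoints: baseline, week 4 (end of first treatment arm),
#: week 12 (after eight weeks of the combination arm).
TIMEPOINTS = ("t0", "t1", "t2")


@dataclass(frozen=True)
class Site:
    """One anatomical site: numeric code, human-readable name, region group."""

    code: int
    name: str
    region: str


class SiteTaxonomy:
    """The fixed 15-site code system.

    Lookup by code is total over the 15 codes and raises ``KeyError``
    (with the offending code in the message) for any other value.
    """

    def __init__(self, sites: list[Site]):
        self._by_code: dict[int, Site] = {}
        for s in sites:
            if s.region not in REGIONS:
                raise ValueError(f"unknown region {s.region!r}")
            if s.code in self._by_code:
                raise ValueError(f"duplicate site code {s.code}")
            self._by_code[s.code] = s

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(sorted(self._by_code))

    def __len__(self) -> int:
        return len(self._by_code)

    def __contains__(self, code: int) -> bool:
        return int(code) in self._by_code

    def __getitem__(self, code: int) -> Site:
        try:
            return self._by_code[int(code)]
        except KeyError:
            raise KeyError(f"unknown site code {code}") from None

    def region_of(self, code: int) -> str:
        """Region label ('peritoneal', 'lymph_node' or 'other') for a code."""
        return self[code].region

    def codes_in_region(self, region: str) -> tuple[int, ...]:
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return tuple(sorted(c for c, s in self._by_code.items() if s.region == region))


def _load_default() -> SiteTaxonomy:
    text = resources.files("metresponse.data").joinpath("site_taxonomy.json").read_text()
    raw = json.loads(text)
    return SiteTaxonomy([Site(int(e["code"]), e["name"], e["region"]) for e in raw["sites"]])


#: The package-wide default taxonomy (the study's 15 codes).
DEFAULT_TAXONOMY = _load_default()


def region_of(site_code: int) -> str:
    """Region of a site code under the default taxonomy."""
    return DEFAULT_TAXONOMY.region_of(site_code)
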