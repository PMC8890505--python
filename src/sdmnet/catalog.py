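"""Fixed vocabularies shared across the analysis.

The behavioral catalogue is the eight-act ethogram scored in staged
same-sex zebrafish contests; the region list is the 19 nuclei of the
social decision-making network (SDMN) plus habenula in which pS6-positive
cells are counted.
"""

from __future__ import annotations

# Ethogram: the eight scored behavioral acts.
BEHAVIORS: tuple[str, ...] = (
    "bite",
    "antiparallel_display",
    "circle",
    "chase",
    "flee",
    "strike",
    "retreat",
    "freeze",
)

# Aggregate definitions used for per-dyad frequency summaries.
AGGRESSIVE_BEHAVIORS: tuple[str, ...] = (
    "antiparallel_display",
    "circle",
    "bite",
    "chase",
    "strike",
)
SUBMISSIVE_BEHAVIORS: tuple[str, ...] = ("freeze", "flee", "retreat")

# SDMN nuclei (telencephalic + diencephalic) plus dorsal/ventral habenula.
REGIONS: tuple[str, ...] = (
    "Dm_m",
    "Dm_l",
    "Dm",
    "Dl",
    "Vv_r",
    "Vv_c",
    "Vd_r",
    "Vd_c",
    "Vs",
    "Vc",
    "PPa_m",
    "PPa_l",
    "PPp",
    "PM",
    "Hv",
    "aTn",
    "TPp",
    "Ha_v",
    "Ha_d",
)

# Rostral/anterior and caudal/posterior suffixes are treated as synonymous
# region labels (e.g. Vv_a == Vv_r, Vd_p == Vd_c).  Keys are stored in a
# normalized form: lower-case with separators removed.
_SUFFIX_SYNONYMS = {"a": "r", "p": "c"}

SEXES: tuple[str, ...] = ("F", "M")
CONDITIONS: tuple[str, ...] = ("control", "winner", "loser")


def _normalize(name: str) -> str:
    return name.replace("_", "").replace(" ", "").replace("-", "").lower()


_CANONICAL_BY_NORM = {_normalize(r): r for r in REGIONS}
# Add alias spellings: swap rostral/caudal suffix for anterior/posterior.
for _region in REGIONS:
    if "_" in _region:
        _stem, _suffix = _region.rsplit("_", 1)
        for _alias, _canon in _SUFFIX_SYNONYMS.items():
            if _suffix == _canon:
                _CANONICAL_BY_NORM[_normalize(f"{_stem}_{_alias}")] = _region


def canonical_region(name: str) -> str:
    """Map a region label (any common spelling) to its canonical name.

    Accepts case/underscore/space variants and the anterior/posterior
    synonyms of the rostral/caudal suffixes, e.g. ``"Vv a"`` -> ``"Vv_r"``,
    ``"Hav"`` -> ``"Ha_v"``.

    Raises
    ------
    KeyError
        If the label cannot be resolved to one of the 19 regions.
    """
    norm = _normalize(name)
    if norm in _CANONICAL_BY_NORM:
        return _CANONICAL_BY_NORM[norm]
    raise KeyError(f"unknown brain region label: {name!r}")
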