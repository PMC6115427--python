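"""Fixed vocabulary of the eight-condition BH3-mimetic panel.

The panel crosses three selective inhibitors — ABT-199 (BCL-2),
WEHI-539 (BCL-X_L), A-1210477 (MCL-1) — in every single, double and
triple combination, plus a vehicle control.  Condition labels are a
closed vocabulary; common drug names map onto it through an alias
table and anything unrecognised fails loudly.
"""

from __future__ import annotations

VEHICLE = "VEH"

#: The seven treatment conditions, in panel order.
TREATMENT_CONDITIONS: tuple[str, ...] = (
    "A199",
    "W539",
    "A121",
    "A199+W539",
    "A199+A121",
    "W539+A121",
    "TRIPLE",
)

CONDITIONS: tuple[str, ...] = (VEHICLE,) + TREATMENT_CONDITIONS

#: Anti-apoptotic targets inhibited under each treatment condition.
CONDITION_TARGETS: dict[str, frozenset[str]] = {
    "A199": frozenset({"BCL2"}),
    "W539": frozenset({"BCLXL"}),
    "A121": frozenset({"MCL1"}),
    "A199+W539": frozenset({"BCL2", "BCLXL"}),
    "A199+A121": frozenset({"BCL2", "MCL1"}),
    "W539+A121": frozenset({"BCLXL", "MCL1"}),
    "TRIPLE": frozenset({"BCL2", "BCLXL", "MCL1"}),
}

#: Latent single-protein dependency phenotypes.
PHENOTYPES: tuple[str, ...] = ("BCL2", "BCLXL", "MCL1")

_CONDITION_ALIASES: dict[str, str] = {
    "VEH": VEHICLE,
    "VEHICLE": VEHICLE,
    "DMSO": VEHICLE,
    "UNTREATED": VEHICLE,
    "A199": "A199",
    "ABT199": "A199",
    "ABT-199": "A199",
    "VENETOCLAX": "A199",
    "W539": "W539",
    "WEHI539": "W539",
    "WEHI-539": "W539",
    "A121": "A121",
    "A1210477": "A121",
    "A-1210477": "A121",
    "TRIPLE": "TRIPLE",
    "A199+W539+A121": "TRIPLE",
}


def normalize_condition(label: str) -> str:
    """Map a raw condition label onto the fixed panel vocabulary.

    Combination labels are resolved component-wise and re-emitted in
    canonical order (``A199+W539``, never ``W539+A199``).
    Raises ``ValueError`` for anything outside the vocabulary.
    """
    key = label.strip().upper()
    if key in _CONDITION_ALIASES:
        return _CONDITION_ALIASES[key]
    if "+" in key:
        parts = [p.strip() for p in key.split("+")]
        try:
            canon = {_CONDITION_ALIASES[p] for p in parts}
        except KeyError as exc:
            raise ValueError(f"unknown drug in condition label {label!r}: {exc}") from None
        for cond, targets in CONDITION_TARGETS.items():
            if {c for c in cond.split("+")} == canon or (
                cond == "TRIPLE" and canon == {"A199", "W539", "A121"}
            ):
                return cond
        for cond in TREATMENT_CONDITIONS:
            comp = {"TRIPLE": {"A199", "W539", "A121"}}.get(cond, set(cond.split("+")))
            if comp == canon:
                return cond
    raise ValueError(f"unknown panel condition: {label!r}")


#: Gene-symbol aliases used throughout (literature names -> HGNC symbols).
GENE_ALIASES: dict[str, str] = {
    "NOXA": "PMAIP1",
    "BCL-XL": "BCL2L1",
    "BCLXL": "BCL2L1",
    "BCL-X_L": "BCL2L1",
    "BCL-W": "BCL2L2",
    "BCLW": "BCL2L2",
    "BFL-1": "BCL2A1",
    "BFL1": "BCL2A1",
    "SNAIL": "SNAI1",
    "SLUG": "SNAI2",
    "E-CADHERIN": "CDH1",
    "ECADHERIN": "CDH1",
    "N-CADHERIN": "CDH2",
    "NCADHERIN": "CDH2",
}


def normalize_gene(symbol: str) -> str:
    """Resolve a gene symbol through the alias table (case-insensitive).

    Unknown symbols are returned upper-cased as-is: the alias table only
    rewrites names that have a well-known canonical HGNC symbol.
    """
    key = symbol.strip().upper()
    return GENE_ALIASES.get(key, key)
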