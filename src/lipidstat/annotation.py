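"""Lipid shorthand-name parsing and classification.

Targeted lipidomics panels report features with vendor shorthand such as
``FFA(16:0)``, ``PE(P-18:0/20:4)`` or ``TAG52:2-FA18:1``.  This module
parses those names into structured :class:`LipidSpecies` records, assigns
saturation and chain-length categories, and collapses triacylglycerol
(TAG) isotopomer features — the per-acyl-transition TAG records that share
one total carbon:double-bond composition — into single species.

Supported grammar (class codes case-insensitive, whitespace tolerant):

* ``CLASS(CC:DB)`` and ``CLASS CC:DB`` and ``CLASSCC:DB``
* chain-resolved ``CLASS(c1:d1/c2:d2[/c3:d3])``, summed to totals
* ether prefixes ``O-``/``P-`` inside the parentheses mark plasmanyl /
  plasmenyl phosphatidylethanolamines: ``PE(O-38:4)`` -> class PE-O
* TAG isotopomers ``TAGcc:db-FAcc:db``
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core import AbundanceMatrix, ContractError

#: The 21 recognised lipid classes (20 from the complex-lipid panel, with
#: ceramides and acylcarnitines quantified by a separate targeted method).
CLASS_REGISTRY = (
    "CE", "MAG", "DAG", "TAG", "FFA",
    "PC", "PE", "PE-O", "PE-P", "PI", "PG",
    "LPC", "PS", "LPS", "LPE",
    "SM", "HCER", "LCER", "DCER", "CER", "AC",
)

ETHER_CLASSES = {"PE-O": "O", "PE-P": "P"}


class LipidParseError(ValueError):
    """A lipid name does not match the supported grammar."""


class UnknownClassError(LipidParseError):
    """The class code is not in the registry."""


@dataclass(frozen=True)
class LipidSpecies:
    """Parsed identity of one measured lipid feature."""

    raw_name: str
    class_code: str
    total_carbons: int
    total_double_bonds: int
    ether_type: str = "none"  # none | O (plasmanyl) | P (plasmenyl)
    sn_fatty_acid: Optional[str] = None  # e.g. "FA18:1" on TAG isotopomers

    def __post_init__(self) -> None:
        if self.class_code not in CLASS_REGISTRY:
            raise UnknownClassError(f"unknown lipid class {self.class_code!r}")
        if self.total_carbons < 2:
            raise LipidParseError(f"{self.raw_name}: carbons must be >= 2")
        if self.total_double_bonds < 0:
            raise LipidParseError(f"{self.raw_name}: double bonds must be >= 0")
        if self.total_double_bonds > self.total_carbons:
            raise LipidParseError(
                f"{self.raw_name}: double bonds ({self.total_double_bonds}) exceed "
                f"carbons ({self.total_carbons})"
            )
        expected_ether = ETHER_CLASSES.get(self.class_code, "none")
        if self.ether_type != expected_ether:
            raise LipidParseError(
                f"{self.raw_name}: ether_type {self.ether_type!r} inconsistent with "
                f"class {self.class_code}"
            )

    def render(self) -> str:
        """Canonical shorthand for this species (parse -> render round-trips)."""
        if self.class_code == "TAG" and self.sn_fatty_acid is not None:
            return (
                f"TAG{self.total_carbons}:{self.total_double_bonds}-{self.sn_fatty_acid}"
            )
        if self.ether_type in ("O", "P"):
            return f"PE({self.ether_type}-{self.total_carbons}:{self.total_double_bonds})"
        return f"{self.class_code}({self.total_carbons}:{self.total_double_bonds})"


_CHAIN = re.compile(r"^(\d+):(\d+)$")
# CLASS(...) | CLASS ... | CLASScc:db, optional -FAcc:db suffix
_NAME = re.compile(
    r"""^\s*
        (?P<cls>[A-Za-z]+(?:-[OP])?)          # class code, possibly PE-O/PE-P
        \s*
        (?:\(\s*(?P<paren>[^()]*?)\s*\)       # parenthesised chain spec
          |(?P<bare>\d+:\d+)                  # or bare cc:db
        )
        (?:\s*-\s*(?P<sn>FA\s*\d+:\d+))?      # optional TAG isotopomer tag
        \s*$""",
    re.VERBOSE,
)


def _parse_chain(token: str, raw: str) -> tuple[int, int]:
    m = _CHAIN.match(token.strip())
    if m is None:
        raise LipidParseError(f"{raw!r}: malformed chain token {token!r}")
    return int(m.group(1)), int(m.group(2))


def parse_lipid_name(raw_name: str) -> LipidSpecies:
    """Parse a vendor shorthand lipid name into a :class:`LipidSpecies`.

    Raises :class:`LipidParseError` for malformed names (naming the
    offending token) and :class:`UnknownClassError` for class codes absent
    from the registry.
    """
    if not raw_name or not raw_name.strip():
        raise LipidParseError("empty lipid name")
    m = _NAME.match(raw_name)
    if m is None:
        raise LipidParseError(f"{raw_name!r}: does not match the lipid-name grammar")

    cls = m.group("cls").upper()
    ether = "none"
    spec = m.group("paren") if m.group("paren") is not None else m.group("bare")
    if not spec:
        raise LipidParseError(f"{raw_name!r}: missing chain specification")

    # ether prefix inside the parentheses: PE(O-38:4), PE(P-18:0/20:4)
    em = re.match(r"^\s*([OP])-\s*(.*)$", spec, re.IGNORECASE)
    if em is not None:
        ether = em.group(1).upper()
        spec = em.group(2)
        if cls == "PE":
            cls = f"PE-{ether}"

    if cls not in CLASS_REGISTRY:
        raise UnknownClassError(f"{raw_name!r}: unknown lipid class {m.group('cls')!r}")
    if cls in ETHER_CLASSES:
        ether = ETHER_CLASSES[cls]
    elif ether != "none":
        raise LipidParseError(
            f"{raw_name!r}: ether prefix only valid for PE-O/PE-P classes"
        )

    chains = [_parse_chain(tok, raw_name) for tok in spec.split("/")]
    carbons = sum(c for c, _ in chains)
    bonds = sum(d for _, d in chains)

    sn = m.group("sn")
    if sn is not None:
        if cls != "TAG":
            raise LipidParseError(
                f"{raw_name!r}: -FA isotopomer suffix only valid for TAG features"
            )
        fc, fd = _parse_chain(re.sub(r"^FA\s*", "", sn), raw_name)
        sn = f"FA{fc}:{fd}"

    return LipidSpecies(
        raw_name=raw_name,
        class_code=cls,
        total_carbons=carbons,
        total_double_bonds=bonds,
        ether_type=ether,
        sn_fatty_acid=sn,
    )


# -- saturation -----------------------------------------------------------

SATURATION_VALUES = ("saturated", "monounsaturated", "polyunsaturated")


def classify_saturation(species: LipidSpecies) -> str:
    """saturated (0 double bonds) / monounsaturated (1) / polyunsaturated (>=2).

    "Unsaturated" as used for class-level strata is the union of mono- and
    polyunsaturated, i.e. at least one double bond.
    """
    db = species.total_double_bonds
    if db == 0:
        return "saturated"
    if db == 1:
        return "monounsaturated"
    return "polyunsaturated"


def is_unsaturated(species: LipidSpecies) -> bool:
    return species.total_double_bonds >= 1


# -- chain length ---------------------------------------------------------

CHAIN_SCHEMES = ("acylcarnitine", "ffa")


def classify_chain_length(species: LipidSpecies, scheme: str) -> Optional[str]:
    """Chain-length category under a named scheme, or None when excluded.

    ``acylcarnitine``: C5-C14 -> intermediate, C16-C20 -> long (the two
    windows of the beta-oxidation ratio); C<5 -> short, C>20 -> very_long,
    and C15 falls in neither window -> None (excluded from the ratio).
    ``ffa``: C16-C24 -> long, otherwise short.
    """
    if scheme not in CHAIN_SCHEMES:
        raise ContractError(f"unknown chain-length scheme {scheme!r}")
    c = species.total_carbons
    if scheme == "acylcarnitine":
        if species.class_code != "AC":
            raise ContractError(
                f"acylcarnitine scheme requires class AC, got {species.class_code}"
            )
        if c < 5:
            return "short"
        if 5 <= c <= 14:
            return "intermediate"
        if 16 <= c <= 20:
            return "long"
        if c > 20:
            return "very_long"
        return None  # C15: in neither stated window
    # ffa scheme
    if species.class_code != "FFA":
        raise ContractError(f"ffa scheme requires class FFA, got {species.class_code}")
    return "long" if 16 <= c <= 24 else "short"


# -- TAG isotopomer collapse ----------------------------------------------

def collapse_tag_isotopomers(
    features: list[LipidSpecies], abundances: AbundanceMatrix
) -> tuple[list[LipidSpecies], AbundanceMatrix, dict[str, list[str]]]:
    """Sum TAG isotopomer features sharing one (carbons, double-bonds) total.

    Vendor panels report TAGs once per constituent fatty-acyl transition;
    all features with the same total composition are summed per sample into
    one ``TAGcc:db`` species.  Non-TAG features pass through unchanged.
    Returns (collapsed species list, collapsed matrix, mapping of collapsed
    name -> member raw names).  Per-sample total TAG abundance is conserved
    exactly (a sum is a reordering of additions).
    """
    abundances.require_stage("concentration", "normalized")
    by_name = {sp.raw_name: sp for sp in features}
    if set(by_name) != set(abundances.feature_names):
        raise ContractError("feature list does not match abundance matrix rows")

    groups: dict[tuple[int, int], list[LipidSpecies]] = {}
    order: list[str] = []  # output feature order: first appearance
    mapping: dict[str, list[str]] = {}
    for sp in features:
        if sp.class_code != "TAG":
            continue
        groups.setdefault((sp.total_carbons, sp.total_double_bonds), []).append(sp)

    for key, members in groups.items():
        tagged = [m for m in members if m.sn_fatty_acid is not None]
        untagged = [m for m in members if m.sn_fatty_acid is None]
        if tagged and untagged:
            raise ContractError(
                f"TAG{key[0]}:{key[1]}: untagged TAG feature collides with "
                f"isotopomer-tagged features of the same composition"
            )

    new_rows: dict[str, pd.Series] = {}
    new_species: list[LipidSpecies] = []
    done: set[tuple[int, int]] = set()
    for sp in features:
        if sp.class_code != "TAG" or sp.sn_fatty_acid is None:
            new_rows[sp.raw_name] = abundances.data.loc[sp.raw_name]
            new_species.append(sp)
            order.append(sp.raw_name)
            continue
        key = (sp.total_carbons, sp.total_double_bonds)
        if key in done:
            continue
        done.add(key)
        members = groups[key]
        name = f"TAG{key[0]}:{key[1]}"
        member_names = [m.raw_name for m in members]
        # NaN-aware sum: all-missing stays missing, partial sums over observed
        block = abundances.data.loc[member_names]
        summed = block.sum(axis=0, skipna=True)
        summed[block.isna().all(axis=0)] = float("nan")
        new_rows[name] = summed
        new_species.append(
            LipidSpecies(
                raw_name=name,
                class_code="TAG",
                total_carbons=key[0],
                total_double_bonds=key[1],
            )
        )
        order.append(name)
        mapping[name] = member_names

    data = pd.DataFrame(new_rows).T.loc[order]
    data.columns = abundances.data.columns
    out = AbundanceMatrix(
        data=data,
        samples=abundances.samples.copy(),
        stage=abundances.stage,
        log=abundances.log
        + [f"collapse_tag_isotopomers: {abundances.n_features} -> {len(order)} features"],
    )
    return new_species, out, mapping


# -- annotation tables -----------------------------------------------------

def annotate_panel(feature_names: list[str]) -> pd.DataFrame:
    """Parse every feature name and tabulate its annotation.

    Columns: feature, class, carbons, double_bonds, ether_type, saturation.
    """
    rows = []
    for name in feature_names:
        sp = parse_lipid_name(name)
        rows.append(
            {
                "feature": name,
                "class": sp.class_code,
                "carbons": sp.total_carbons,
                "double_bonds": sp.total_double_bonds,
                "ether_type": sp.ether_type,
                "saturation": classify_saturation(sp),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="feature")


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, index=True)
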