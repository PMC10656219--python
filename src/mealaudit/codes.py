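"""FNDDS food codes and major food groups.

The USDA Food and Nutrient Database for Dietary Studies (FNDDS) assigns
every food an 8-digit hierarchical code whose first digit indexes the
major food group (1 = milk and milk products ... 9 = sugars, sweets, and
beverages).  Codes are handled as strings throughout so that leading
zeros in the trailing digits and digit-position semantics survive I/O.
"""

from __future__ import annotations

from dataclasses import dataclass


class FnddsCodeError(ValueError):
    """Raised when a string cannot be interpreted as an FNDDS code."""


@dataclass(frozen=True)
class FoodGroup:
    """A major FNDDS food group (first code digit)."""

    id: int
    label: str


FOOD_GROUPS: dict[int, FoodGroup] = {
    1: FoodGroup(1, "milk and milk products"),
    2: FoodGroup(2, "meat, poultry, fish, and mixtures"),
    3: FoodGroup(3, "eggs"),
    4: FoodGroup(4, "dry beans, peas, other legumes, nuts, and seeds"),
    5: FoodGroup(5, "grain products"),
    6: FoodGroup(6, "fruits"),
    7: FoodGroup(7, "vegetables"),
    8: FoodGroup(8, "fats, oils, and salad dressings"),
    9: FoodGroup(9, "sugars, sweets, and beverages"),
}


class FnddsCode(str):
    """A validated 8-digit FNDDS code.

    Subclasses :class:`str`, so codes compare, hash and serialise like
    plain strings while guaranteeing the format invariants:

    * exactly 8 characters, all decimal digits;
    * first digit in 1..9 (a defined major food group).
    """

    __slots__ = ()

    def __new__(cls, text: str) -> "FnddsCode":
        if not isinstance(text, str) or not text:
            raise FnddsCodeError("FNDDS code must be a non-empty string")
        if len(text) != 8:
            raise FnddsCodeError(
                f"FNDDS code {text!r}: expected 8 digits, got length {len(text)}"
            )
        if not text.isdigit():
            raise FnddsCodeError(f"FNDDS code {text!r}: non-digit characters")
        if text[0] == "0":
            raise FnddsCodeError(
                f"FNDDS code {text!r}: first digit must be 1-9 (major food group)"
            )
        return super().__new__(cls, text)

    @property
    def group(self) -> FoodGroup:
        return FOOD_GROUPS[int(self[0])]


def parse_fndds_code(text: str) -> FnddsCode:
    """Validate ``text`` as an 8-digit FNDDS code.

    >>> parse_fndds_code("27510170").group.id
    2
    """
    return FnddsCode(text)


def major_group(code: FnddsCode | str) -> FoodGroup:
    """Major food group of ``code`` (the numeric value of its first digit)."""
    return FnddsCode(code).group
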