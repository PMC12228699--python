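"""The closed five-class taste vocabulary.

Taste classes are sweet, bitter, sour, umami, and undefined, in a fixed
order that every probability vector, confusion matrix and metrics table in
the package shares. ``undefined`` absorbs tasteless, salty, ambiguous and
out-of-domain molecules; salty is not a structural class because it is
mediated by ion properties rather than molecular shape.
"""

from __future__ import annotations

import enum


class TasteLabel(enum.Enum):
    """One of the five admissible taste classes, with a stable index 0-4."""

    SWEET = "sweet"
    BITTER = "bitter"
    SOUR = "sour"
    UMAMI = "umami"
    UNDEFINED = "undefined"

    @property
    def index(self) -> int:
        return _LABEL_ORDER.index(self)

    @classmethod
    def from_string(cls, text: str) -> "TasteLabel":
        """Parse a label string; anything outside the five classes fails.

        Raises
        ------
        ValueError
            If ``text`` is not one of the admissible label strings.
        """
        try:
            return cls(text.strip().lower())
        except ValueError:
            raise ValueError(
                f"unknown taste label {text!r}; expected one of "
                f"{[l.value for l in _LABEL_ORDER]}"
            ) from None

    @classmethod
    def from_index(cls, index: int) -> "TasteLabel":
        return _LABEL_ORDER[index]

    def __str__(self) -> str:
        return self.value


_LABEL_ORDER = (
    TasteLabel.SWEET,
    TasteLabel.BITTER,
    TasteLabel.SOUR,
    TasteLabel.UMAMI,
    TasteLabel.UNDEFINED,
)

#: Fixed label order used everywhere a vector over classes appears.
LABEL_ORDER = _LABEL_ORDER

#: Number of taste classes.
N_CLASSES = len(LABEL_ORDER)


class Abstain:
    """Sentinel for a withheld prediction (consensus threshold unmet)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSTAIN"


#: Singleton abstention marker returned by consensus prediction.
ABSTAIN = Abstain()
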