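"""Vertebra code set, anatomical ordering, and the segmentation label scheme.

Codes follow the usual clinical enumeration C1-C7, T1-T12, L1-L5, ordered
cranial to caudal. Segmentation masks store one integer per vertebra (C1=1 ..
L5=24, the VerSe convention) and a distinct code for the trabecular
subregion of each vertebral body, offset by ``TRABECULAR_OFFSET``.
"""

from __future__ import annotations

from .errors import ValidationError

VERTEBRA_CODES: tuple[str, ...] = tuple(
    [f"C{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
)

#: Vertebra code -> integer mask label (1-based, cranial to caudal).
LABEL_OF: dict[str, int] = {c: i + 1 for i, c in enumerate(VERTEBRA_CODES)}

#: Added to a vertebra's label to mark its trabecular compartment.
TRABECULAR_OFFSET = 100

#: Contrast phases, in the fixed tie-break order used throughout the package.
PHASES: tuple[str, str, str] = ("NE", "AR", "PV")

#: Slice-selection levels used by the anatomy-guided classifier input.
DEFAULT_INPUT_LEVELS: tuple[str, ...] = ("T8", "T9", "T10", "T11", "T12", "L1", "L2")

#: Levels contributing to the lumbar BMD average.
LUMBAR_BMD_LEVELS: tuple[str, str, str] = ("L1", "L2", "L3")


def check_level(code: str) -> str:
    """Return ``code`` if it is a valid vertebra code, else raise."""
    if code not in LABEL_OF:
        raise ValidationError(f"unknown vertebra code: {code!r}")
    return code


def level_index(code: str) -> int:
    """Cranial-to-caudal sort key for a vertebra code."""
    check_level(code)
    return LABEL_OF[code] - 1


def vertebra_label(code: str) -> int:
    """Mask label of the whole vertebra (cortical shell + posterior elements)."""
    return LABEL_OF[check_level(code)]


def trabecular_label(code: str) -> int:
    """Mask label of the trabecular compartment of a vertebral body."""
    return LABEL_OF[check_level(code)] + TRABECULAR_OFFSET


def check_phase(phase: str) -> str:
    if phase not in PHASES:
        raise ValidationError(f"unknown contrast phase: {phase!r}")
    return phase
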