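"""ICD-9 code semantics for diabetes-type phenotyping.

Diabetes encounter codes live in chapter 250; the fifth digit carries the
type information: 250.x1 and 250.x3 are type 1 codes, 250.x0 and 250.x2 are
type 2 codes.  Pregnancy-related diagnoses occupy chapters 630-676 and
delivery procedure codes the range 72-75; both drive the gestational
exclusion windows of the cohort builder.
"""

from __future__ import annotations

TYPE1 = "type1"
TYPE2 = "type2"
OTHER = "other"

_T1_SUFFIX = frozenset("13")
_T2_SUFFIX = frozenset("02")

PREGNANCY_RANGE = (630, 676)
DELIVERY_RANGE = (72, 75)


def normalize_icd9(code: str) -> str:
    """Normalize an undotted claims-dialect code to dotted form.

    "25001" -> "250.01"; codes already containing a dot, codes of at most
    three characters, and non-numeric strings pass through unchanged.
    """
    code = code.strip()
    if "." in code or len(code) <= 3 or not code[:3].isdigit():
        return code
    return code[:3] + "." + code[3:]


def code_type(icd9: str) -> str:
    """Classify an ICD-9 code string as ``type1``, ``type2`` or ``other``.

    Only well-formed five-digit diabetes codes (250.x0-250.x3, dotted form)
    map to a type; three- and four-digit 250 codes and everything else map
    to ``other``.  Total function: never raises.
    """
    code = icd9.strip()
    if not code.startswith("250.") or len(code) != 6:
        return OTHER
    fourth, fifth = code[4], code[5]
    if not fourth.isdigit():
        return OTHER
    if fifth in _T1_SUFFIX:
        return TYPE1
    if fifth in _T2_SUFFIX:
        return TYPE2
    return OTHER


def _chapter(icd9: str) -> int | None:
    """Integer value of the text before the first dot, or None."""
    head = icd9.strip().split(".", 1)[0]
    if not head.isdigit():
        return None
    return int(head)


def is_pregnancy_code(icd9: str) -> bool:
    """True iff the chapter prefix falls in the pregnancy range 630-676."""
    ch = _chapter(icd9)
    return ch is not None and PREGNANCY_RANGE[0] <= ch <= PREGNANCY_RANGE[1]


def is_delivery_code(icd9: str) -> bool:
    """True iff the chapter prefix falls in the delivery range 72-75.

    The range is axis-agnostic: it is applied to whatever code string is
    recorded on the encounter, whether from a diagnosis or procedure axis.
    """
    ch = _chapter(icd9)
    return ch is not None and DELIVERY_RANGE[0] <= ch <= DELIVERY_RANGE[1]
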