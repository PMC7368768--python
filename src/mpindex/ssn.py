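"""National social security number (SSN): structure, check digits, generation.

The 13-digit SSN is ``YYYYMMDDSSSC1C2``: the birth date (8 digits), a
3-digit sequential range disambiguating people born the same day, and two
control digits produced by two separate algorithms. Following the national
number convention, the first control digit ``C1`` is a Luhn check digit
over the 11 leading digits, and the second ``C2`` is a Verhoeff check
digit over the 12 digits that include ``C1``. Together the two codes
detect every single-digit substitution anywhere in the number.

Both algorithms are implemented here from their definitions; the check
functions are exposed individually so alternative schemes can be swapped
in via :func:`generate_ssn`'s ``algorithms`` argument.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

__all__ = [
    "SSN",
    "SSNValidation",
    "luhn_check_digit",
    "verhoeff_check_digit",
    "generate_ssn",
    "validate_ssn",
]

SSN_LENGTH = 13


def luhn_check_digit(digits: str) -> int:
    """Luhn check digit for a digit string (appended digit makes sum ≡ 0 mod 10).

    Walking right-to-left over ``digits``, every other digit (starting with
    the rightmost) is doubled, with digits above 9 reduced by 9.
    """
    total = 0
    for i, ch in enumerate(reversed(digits)):
        d = int(ch)
        if i % 2 == 0:
            d *= 2
            if d > 9:
                d -= 9
        total += d
    return (10 - total % 10) % 10


# Verhoeff tables: multiplication in the dihedral group D5, the fixed
# permutation applied by position, and the group inverse.
_D = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (1, 2, 3, 4, 0, 6, 7, 8, 9, 5),
    (2, 3, 4, 0, 1, 7, 8, 9, 5, 6),
    (3, 4, 0, 1, 2, 8, 9, 5, 6, 7),
    (4, 0, 1, 2, 3, 9, 5, 6, 7, 8),
    (5, 9, 8, 7, 6, 0, 4, 3, 2, 1),
    (6, 5, 9, 8, 7, 1, 0, 4, 3, 2),
    (7, 6, 5, 9, 8, 2, 1, 0, 4, 3),
    (8, 7, 6, 5, 9, 3, 2, 1, 0, 4),
    (9, 8, 7, 6, 5, 4, 3, 2, 1, 0),
)
_P = (
    (0, 1, 2, 3, 4, 5, 6, 7, 8, 9),
    (1, 5, 7, 6, 2, 8, 3, 0, 9, 4),
    (5, 8, 0, 3, 7, 9, 6, 1, 4, 2),
    (8, 9, 1, 6, 0, 4, 3, 5, 2, 7),
    (9, 4, 5, 3, 1, 2, 6, 8, 7, 0),
    (4, 2, 8, 6, 5, 7, 3, 9, 0, 1),
    (2, 7, 9, 3, 8, 0, 6, 4, 1, 5),
    (7, 0, 4, 6, 9, 1, 3, 2, 5, 8),
)
_INV = (0, 4, 3, 2, 1, 5, 6, 7, 8, 9)


def verhoeff_check_digit(digits: str) -> int:
    """Verhoeff check digit: appended digit drives the D5 checksum to identity."""
    c = 0
    # Position 1 is the (future) check digit itself; payload starts at 2.
    for i, ch in enumerate(reversed(digits), start=1):
        c = _D[c][_P[i % 8][int(ch)]]
    return _INV[c]


DEFAULT_ALGORITHMS: Tuple[Callable[[str], int], Callable[[str], int]] = (
    luhn_check_digit,
    verhoeff_check_digit,
)


@dataclass(frozen=True)
class SSN:
    """A parsed, check-valid 13-digit national identifier."""

    raw: str
    year: int
    month: int
    day: int
    sequence: int
    check1: int
    check2: int

    @property
    def birth_date(self) -> _dt.date:
        return _dt.date(self.year, self.month, self.day)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.raw


@dataclass(frozen=True)
class SSNValidation:
    """Validation outcome; ``reason`` is set exactly when ``ok`` is false."""

    ok: bool
    ssn: Optional[SSN] = None
    reason: Optional[str] = None


def generate_ssn(birth_date: _dt.date, sequence: int,
                 algorithms=DEFAULT_ALGORITHMS) -> SSN:
    """Build the SSN for a birth date and sequential range.

    Deterministic: the same (date, sequence) pair always yields the same
    13-digit string. ``sequence`` must lie in 0..999.
    """
    if not isinstance(birth_date, _dt.date):
        raise TypeError("birth_date must be a datetime.date")
    if not 0 <= int(sequence) <= 999:
        raise ValueError("sequence must be in 0..999")
    body = f"{birth_date.year:04d}{birth_date.month:02d}{birth_date.day:02d}{int(sequence):03d}"
    c1 = algorithms[0](body)
    c2 = algorithms[1](body + str(c1))
    return SSN(raw=body + str(c1) + str(c2), year=birth_date.year,
               month=birth_date.month, day=birth_date.day,
               sequence=int(sequence), check1=c1, check2=c2)


def validate_ssn(ssn: str, algorithms=DEFAULT_ALGORITHMS) -> SSNValidation:
    """Parse and check-validate an SSN string.

    Failures are returned, never raised, so ingestion can turn them into
    per-record rejection reasons. Distinct reason codes: ``WRONG_LENGTH``,
    ``NON_NUMERIC``, ``INVALID_DATE``, ``CHECK1_MISMATCH``,
    ``CHECK2_MISMATCH``.
    """
    text = str(ssn).strip()
    if len(text) != SSN_LENGTH:
        return SSNValidation(ok=False, reason="WRONG_LENGTH")
    if not text.isdigit():
        return SSNValidation(ok=False, reason="NON_NUMERIC")
    year, month, day = int(text[0:4]), int(text[4:6]), int(text[6:8])
    try:
        birth = _dt.date(year, month, day)
    except ValueError:
        return SSNValidation(ok=False, reason="INVALID_DATE")
    if algorithms[0](text[:11]) != int(text[11]):
        return SSNValidation(ok=False, reason="CHECK1_MISMATCH")
    if algorithms[1](text[:12]) != int(text[12]):
        return SSNValidation(ok=False, reason="CHECK2_MISMATCH")
    return SSNValidation(ok=True, ssn=SSN(
        raw=text, year=year, month=month, day=day,
        sequence=int(text[8:11]), check1=int(text[11]), check2=int(text[12]),
    ))
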