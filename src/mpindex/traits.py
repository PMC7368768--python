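"""Identity traits: the demographic profile attached to every identity record.

The national chart distinguishes three tiers of traits. *Strict* traits
(first name, last name, birth date, sex) are mandatory: a profile missing
any of them is rejected outright. *Extended* traits (birth place, native
country, addresses, death information) and *complementary* traits (mobile
phone, e-mail) are optional. Every textual trait has a maximum length and
must be representable in ISO-LATIN-1, the encoding of the national feed.

Dates travel as ``DD/MM/YYYY`` on the wire and are held as
:class:`datetime.date` internally.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

from .ssn import SSN, validate_ssn

__all__ = [
    "IdentityTraits",
    "ValidationReport",
    "validate_traits",
    "normalize_name",
    "parse_date",
    "format_date",
    "TRAIT_FIELDS",
    "STRICT_TRAITS",
    "MAX_LENGTHS",
]

DATE_FORMAT = "%d/%m/%Y"

#: Trait columns in national-chart order (identifiers excluded).
TRAIT_FIELDS = (
    "first_name",
    "middle_name",
    "last_name",
    "birth_date",
    "sex",
    "birth_place",
    "native_country",
    "legal_address_line1",
    "legal_address_line2",
    "corr_address_line1",
    "corr_address_line2",
    "death_indicator",
    "death_date",
    "mobile_phone",
    "email",
)

#: Mandatory traits whose absence causes rejection.
STRICT_TRAITS = ("first_name", "last_name", "birth_date", "sex")

#: Maximum character counts per the national chart.
MAX_LENGTHS = {
    "first_name": 100,
    "middle_name": 70,
    "last_name": 70,
    "birth_place": 50,
    "native_country": 3,
    "legal_address_line1": 65,
    "legal_address_line2": 50,
    "corr_address_line1": 65,
    "corr_address_line2": 50,
    "death_indicator": 1,
    "mobile_phone": 20,
    "email": 20,
}

SEX_VALUES = frozenset({"M", "F", "A"})

# Folding table for the five vowels bearing circumflex, acute, grave or
# diaeresis marks (the only folding the platform applies, and only for
# candidate retrieval -- stored traits keep their diacritics).
_FOLD = str.maketrans(
    "àáâäãèéêëìíîïòóôöõùúûüÀÁÂÄÃÈÉÊËÌÍÎÏÒÓÔÖÕÙÚÛÜ",
    "aaaaaeeeeiiiiooooouuuuAAAAAEEEEIIIIOOOOOUUUU",
)


def _latin1_ok(value: str) -> bool:
    try:
        value.encode("iso-8859-1")
    except UnicodeEncodeError:
        return False
    return True


def normalize_name(value: str, fold_diacritics: bool = False) -> str:
    """Canonicalize a name for comparison.

    Trims, collapses internal whitespace, and case-folds. Diacritics are
    preserved unless ``fold_diacritics`` is set, in which case the five
    accented vowels are mapped to their base letters (used for blocking
    keys only, never for stored traits).

    Raises ``ValueError`` if the text is not ISO-LATIN-1 representable.
    """
    if not _latin1_ok(value):
        raise ValueError(f"ENCODING: not ISO-LATIN-1 representable: {value!r}")
    # str.lower (not casefold) keeps the result ISO-LATIN-1 representable
    out = " ".join(value.split()).lower()
    if fold_diacritics:
        out = out.translate(_FOLD)
    return out


def parse_date(value: str) -> _dt.date:
    """Parse a ``DD/MM/YYYY`` date; raises ``ValueError`` on anything else."""
    return _dt.datetime.strptime(value.strip(), DATE_FORMAT).date()


def format_date(value: _dt.date) -> str:
    return value.strftime(DATE_FORMAT)


@dataclass(frozen=True)
class IdentityTraits:
    """The demographic trait set of one identity profile."""

    first_name: str
    last_name: str
    birth_date: _dt.date
    sex: str
    middle_name: Optional[str] = None
    birth_place: Optional[str] = None
    native_country: Optional[str] = None
    legal_address_line1: Optional[str] = None
    legal_address_line2: Optional[str] = None
    corr_address_line1: Optional[str] = None
    corr_address_line2: Optional[str] = None
    death_indicator: Optional[str] = None
    death_date: Optional[_dt.date] = None
    mobile_phone: Optional[str] = None
    email: Optional[str] = None

    def replace(self, **changes) -> "IdentityTraits":
        return dataclasses.replace(self, **changes)

    def to_row(self) -> dict:
        """Serialize to a wire-format row (dates as DD/MM/YYYY strings)."""
        row = {}
        for name in TRAIT_FIELDS:
            value = getattr(self, name)
            if value is None:
                row[name] = ""
            elif isinstance(value, _dt.date):
                row[name] = format_date(value)
            else:
                row[name] = value
        return row


@dataclass
class ValidationReport:
    """Outcome of profile validation: accepted iff no rejection reasons.

    ``warnings`` carry non-blocking observations (e.g. an SSN whose embedded
    date disagrees with the birth-date trait) that are routed to vigilance
    rather than causing rejection.
    """

    accepted: bool
    reasons: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    traits: Optional[IdentityTraits] = None
    ssn: Optional[SSN] = None


def _clean(record: Mapping[str, object], name: str) -> str:
    value = record.get(name, "")
    if value is None:
        return ""
    return str(value).strip()


def validate_traits(record: Mapping[str, object], require_ssn: bool = False) -> ValidationReport:
    """Validate a raw trait map against the national identity chart.

    Total: any input map yields a report, never an exception. Every
    violation is reported as one coded reason; ``accepted`` is true iff
    the reason list is empty. The parsed :class:`IdentityTraits` (and
    :class:`~mpindex.ssn.SSN`, when supplied) are attached on acceptance.

    The SSN is validated whenever present; ``require_ssn=True`` (the
    reference-registry workflow) additionally rejects records lacking one.
    """
    reasons: list[str] = []
    warnings: list[str] = []
    values: dict[str, object] = {}

    for name in STRICT_TRAITS:
        if not _clean(record, name):
            reasons.append(f"MISSING_STRICT_TRAIT:{name}")

    for name in TRAIT_FIELDS:
        raw = _clean(record, name)
        if not raw:
            values[name] = None
            continue
        if not _latin1_ok(raw):
            reasons.append(f"ENCODING:{name}")
            continue
        if name in ("birth_date", "death_date"):
            try:
                values[name] = parse_date(raw)
            except ValueError:
                reasons.append(f"INVALID_DATE:{name}")
            continue
        limit = MAX_LENGTHS.get(name)
        if limit is not None and len(raw) > limit:
            reasons.append(f"FIELD_TOO_LONG:{name}")
            continue
        values[name] = raw

    sex = values.get("sex")
    if sex is not None and sex not in SEX_VALUES:
        reasons.append("INVALID_SEX")
    country = values.get("native_country")
    if country is not None and not (len(country) == 3 and country.isalpha()):
        reasons.append("INVALID_COUNTRY")

    birth = values.get("birth_date")
    if isinstance(birth, _dt.date) and birth > _dt.date.today():
        reasons.append("INVALID_DATE:birth_date")
        birth = None
        values["birth_date"] = None
    death = values.get("death_date")
    if isinstance(death, _dt.date) and isinstance(birth, _dt.date) and death < birth:
        reasons.append("DEATH_BEFORE_BIRTH")

    ssn_raw = _clean(record, "ssn")
    ssn: Optional[SSN] = None
    if ssn_raw:
        outcome = validate_ssn(ssn_raw)
        if outcome.ok:
            ssn = outcome.ssn
            if isinstance(birth, _dt.date) and ssn.birth_date != birth:
                warnings.append("SSN_BIRTHDATE_MISMATCH")
        else:
            reasons.append(f"INVALID_SSN:{outcome.reason}")
    elif require_ssn:
        reasons.append("INVALID_SSN:MISSING")

    accepted = not reasons
    traits = None
    if accepted:
        traits = IdentityTraits(
            first_name=values["first_name"],
            last_name=values["last_name"],
            birth_date=values["birth_date"],
            sex=values["sex"],
            middle_name=values.get("middle_name"),
            birth_place=values.get("birth_place"),
            native_country=values.get("native_country"),
            legal_address_line1=values.get("legal_address_line1"),
            legal_address_line2=values.get("legal_address_line2"),
            corr_address_line1=values.get("corr_address_line1"),
            corr_address_line2=values.get("corr_address_line2"),
            death_indicator=values.get("death_indicator"),
            death_date=values.get("death_date"),
            mobile_phone=values.get("mobile_phone"),
            email=values.get("email"),
        )
    return ValidationReport(accepted=accepted, reasons=reasons, warnings=warnings,
                            traits=traits, ssn=ssn)
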