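"""Synthetic multicultural population and anomaly injection.

The generator emulates the population the index serves: a small country
with a strongly multicultural resident mix, heavy use of diacritics
across Portuguese, French, Italian, Belgian, German and other name
traditions, recurrent homonyms, and a national identifier carried by
almost everyone. Defaults follow the published community shares
(Portuguese 33%, French 16%, Italian 8%, Belgian 7%, German 5%, other
European 16%, non-European 15%).

Anomaly injection emits, for a configured fraction of people, a second
record of the same person corrupted according to a drawn cause:

* ``MARITAL_NAME`` — the last name is replaced by a spouse surname drawn
  from the same nationality pool (alternative use of marital vs family
  name);
* ``SPELLING`` — a single-character typo or diacritic drop in a name;
* ``LOCAL_ID`` — traits unchanged, but the record is presented from a
  different identification domain under a new local identifier and
  without the national identifier;
* ``OTHER`` — a birth-date digit transposition.

Cause proportions default to the observed operational mixture
(29 / 29 / 20 / 22 percent). Every variant carries its true cause label
and a link to its source person, so end-to-end runs can verify that the
vigilance statistics recover the injected mixture.
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .ssn import generate_ssn
from .traits import format_date, parse_date

__all__ = [
    "NAME_POOLS",
    "DEFAULT_NATIONALITY_MIX",
    "DEFAULT_CAUSE_MIX",
    "PopulationConfig",
    "AnomalyConfig",
    "Person",
    "AnomalyVariant",
    "generate_population",
    "inject_anomalies",
    "simulate_days",
]

#: Per-nationality name pools; all entries are ISO-LATIN-1 representable
#: and the pools deliberately carry diacritics.
NAME_POOLS: Dict[str, Dict[str, List[str]]] = {
    "PT": {
        "M": ["José", "João", "António", "Tiago", "Rui", "Nuno", "Pedro",
              "Miguel", "Luís", "Paulo"],
        "F": ["Maria", "Ana", "Conceição", "Fátima", "Sofia", "Inês",
              "Catarina", "Beatriz", "Joana", "Leonor"],
        "surnames": ["Silva", "Santos", "Ferreira", "Pereira", "Oliveira",
                     "Costa", "Rodrigues", "Martins", "Gonçalves",
                     "Fernandes", "Araújo", "Simões"],
        "country": "PRT", "city": "Lisboa",
    },
    "FR": {
        "M": ["François", "Jean", "Pierre", "Michel", "André", "René",
              "Stéphane", "Cédric", "Hervé", "Benoît"],
        "F": ["Hélène", "Amélie", "Cécile", "Chloé", "Françoise", "Agnès",
              "Anaïs", "Noémie", "Eugénie", "Léa"],
        "surnames": ["Dupont", "Moreau", "Lefèvre", "Durand", "Bernard",
                     "Petit", "Rousseau", "Fontaine", "Chevalier", "Gérard"],
        "country": "FRA", "city": "Metz",
    },
    "IT": {
        "M": ["Giovanni", "Niccolò", "Andrea", "Matteo", "Luca",
              "Alessandro", "Francesco", "Marco"],
        "F": ["Giulia", "Chiara", "Francesca", "Alessia", "Martina",
              "Elena", "Sara", "Valentina"],
        "surnames": ["Rossi", "Russo", "Ferrari", "Esposito", "Bianchi",
                     "Romano", "Colombo", "Ricci"],
        "country": "ITA", "city": "Milano",
    },
    "BE": {
        "M": ["Luc", "Koen", "Wim", "Bart", "Thomas", "Maxime", "Jérôme"],
        "F": ["Els", "Anne", "Marie", "Sofie", "Lien", "Aurélie", "Mieke"],
        "surnames": ["Peeters", "Janssens", "Maes", "Jacobs", "Mertens",
                     "Willems", "Claes", "Dubois"],
        "country": "BEL", "city": "Arlon",
    },
    "DE": {
        "M": ["Hans", "Jürgen", "Klaus", "Günter", "Jörg", "Stefan",
              "Andreas", "Matthias"],
        "F": ["Ursula", "Käthe", "Ingrid", "Heike", "Sabine", "Anja", "Jutta"],
        "surnames": ["Müller", "Schäfer", "Schröder", "Weiß", "Böhm",
                     "Krüger", "Schmidt", "Fischer", "Wagner", "Köhler"],
        "country": "DEU", "city": "Trier",
    },
    "LU": {
        "M": ["Pol", "Jang", "Claude", "Marc", "Fernand", "Romain"],
        "F": ["Josée", "Margot", "Christiane", "Danielle", "Liss", "Netty"],
        "surnames": ["Schmit", "Weber", "Muller", "Hoffmann", "Faber",
                     "Reuter", "Kieffer", "Thill", "Majerus", "Wagener"],
        "country": "LUX", "city": "Luxembourg",
    },
    "OTHER_EU": {
        "M": ["Jan", "Piet", "Sven", "Lars", "Søren", "Ramón", "Andrés",
              "Henk"],
        "F": ["Eva", "Marta", "Lucía", "Åsa", "Mette", "Sanne", "Birgit"],
        "surnames": ["González", "Fernández", "Jansen", "Hansen", "Nielsen",
                     "Ibáñez", "Muñoz", "Visser"],
        "country": "ESP", "city": "Esch-sur-Alzette",
    },
    "NON_EU": {
        "M": ["Ahmed", "Mehmet", "Ali", "Omar", "Sergei", "Andrei", "Chen",
              "Raj"],
        "F": ["Fatima", "Aisha", "Yasmin", "Olga", "Irina", "Mei", "Priya"],
        "surnames": ["Yilmaz", "Haddad", "Ivanov", "Petrov", "Khan",
                     "Nguyen", "Wang", "Diallo"],
        "country": "TUR", "city": "Differdange",
    },
}

#: Published community shares, used verbatim as the default mix.
DEFAULT_NATIONALITY_MIX: Dict[str, float] = {
    "PT": 0.33, "FR": 0.16, "IT": 0.08, "BE": 0.07, "DE": 0.05,
    "OTHER_EU": 0.16, "NON_EU": 0.15,
}

#: Observed anomaly-cause mixture (marital/family-name alternation,
#: spelling mistakes, divergent local identifiers, everything else).
DEFAULT_CAUSE_MIX: Dict[str, float] = {
    "MARITAL_NAME": 0.29, "SPELLING": 0.29, "LOCAL_ID": 0.20, "OTHER": 0.22,
}


@dataclass
class PopulationConfig:
    """Parameters of one synthetic population draw.

    ``homonym_rate`` is the probability that a person reuses an existing
    (first, last) name pair — homonym pressure exercises the ambiguity
    branches of the matcher. ``growth_rate`` (annual percent) is consumed
    by the day simulator to ramp daily volumes.
    """

    n: int = 1000
    nationality_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NATIONALITY_MIX))
    homonym_rate: float = 0.05
    growth_rate: float = 2.0
    birth_years: tuple = (1920, 2005)
    seed: int = 0

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("population size must be positive")
        total = sum(self.nationality_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("nationality proportions must sum to 1")
        unknown = set(self.nationality_mix) - set(NAME_POOLS)
        if unknown:
            raise ValueError(f"no name pool for nationalities {sorted(unknown)}")


@dataclass
class AnomalyConfig:
    """Anomaly injection parameters: overall fraction and cause mixture."""

    fraction: float = 0.1
    cause_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CAUSE_MIX))
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("corruption fraction must be in [0, 1]")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cause proportions must sum to 1")


@dataclass
class Person:
    """One synthetic identity: the delta row plus generator ground truth."""

    person_id: int
    nationality: str
    row: dict

    @property
    def ssn(self) -> str:
        return self.row["ssn"]


@dataclass
class AnomalyVariant:
    """A corrupted re-presentation of a person, with its true cause label."""

    source: Person
    cause: str
    row: dict


def _draw(rng: random.Random, mix: Dict[str, float]) -> str:
    labels = sorted(mix)
    return rng.choices(labels, weights=[mix[k] for k in labels], k=1)[0]


def generate_population(config: PopulationConfig) -> List[Person]:
    """Draw a validator-clean population: every record carries all strict
    traits, a check-valid SSN, and nationality-appropriate names.
    Deterministic for a fixed seed.
    """
    rng = random.Random(config.seed)
    y0, y1 = config.birth_years
    day0 = _dt.date(y0, 1, 1).toordinal()
    day1 = _dt.date(y1, 12, 31).toordinal()
    seq_by_date: Dict[_dt.date, int] = {}
    used_names: List[tuple] = []
    persons: List[Person] = []

    for i in range(config.n):
        nationality = _draw(rng, config.nationality_mix)
        pool = NAME_POOLS[nationality]
        sex = rng.choices(["M", "F", "A"], weights=[49.5, 49.5, 1.0], k=1)[0]
        name_sex = sex if sex in ("M", "F") else rng.choice(["M", "F"])
        if used_names and rng.random() < config.homonym_rate:
            first, last = rng.choice(used_names)
        else:
            first = rng.choice(pool[name_sex])
            last = rng.choice(pool["surnames"])
            if rng.random() < 0.08:  # hyphenated compound surnames occur
                other = rng.choice(pool["surnames"])
                if other != last:
                    last = f"{last}-{other}"
        used_names.append((first, last))

        birth = _dt.date.fromordinal(rng.randrange(day0, day1 + 1))
        seq = seq_by_date.get(birth, 0)
        seq_by_date[birth] = seq + 1
        ssn = generate_ssn(birth, seq)

        row = {
            "ssn": ssn.raw,
            "first_name": first,
            "middle_name": "",
            "last_name": last,
            "birth_date": format_date(birth),
            "sex": sex,
            "birth_place": pool["city"],
            "native_country": pool["country"],
            "legal_address_line1": f"{rng.randrange(1, 200)} rue de la Gare",
            "legal_address_line2": "",
            "corr_address_line1": "",
            "corr_address_line2": "",
            "death_indicator": "",
            "death_date": "",
            "mobile_phone": "",
            "email": "",
        }
        persons.append(Person(person_id=i, nationality=nationality, row=row))
    return persons


_LETTERS = "abcdefghijklmnopqrstuvwxyz"
_DIACRITIC_BASE = dict(zip("àáâäãèéêëìíîïòóôöõùúûü",
                           "aaaaaeeeeiiiiooooouuuu"))


def _typo(rng: random.Random, name: str) -> str:
    """One-character substitution; drops a diacritic when one is present."""
    marked = [i for i, ch in enumerate(name) if ch.lower() in _DIACRITIC_BASE]
    if marked and rng.random() < 0.5:
        i = rng.choice(marked)
        base = _DIACRITIC_BASE[name[i].lower()]
        repl = base.upper() if name[i].isupper() else base
    else:
        candidates = [i for i, ch in enumerate(name) if ch.isalpha()]
        i = rng.choice(candidates)
        repl = rng.choice([c for c in _LETTERS if c != name[i].lower()])
        if name[i].isupper():
            repl = repl.upper()
    return name[:i] + repl + name[i + 1:]


def _transpose_birth_date(rng: random.Random, text: str) -> str:
    """Swap two adjacent digits of a DD/MM/YYYY date, keeping it a valid,
    different, non-future calendar date; falls back to shifting the day.
    """
    original = parse_date(text)
    digits = text.replace("/", "")
    positions = list(range(len(digits) - 1))
    rng.shuffle(positions)
    for i in positions:
        if digits[i] == digits[i + 1]:
            continue
        swapped = digits[:i] + digits[i + 1] + digits[i] + digits[i + 2:]
        candidate = f"{swapped[:2]}/{swapped[2:4]}/{swapped[4:]}"
        try:
            parsed = parse_date(candidate)
        except ValueError:
            continue
        if parsed != original and parsed <= _dt.date.today():
            return candidate
    shifted = original.replace(day=(original.day % 28) + 1)
    return format_date(shifted)


def inject_anomalies(persons: Sequence[Person],
                     config: AnomalyConfig) -> List[AnomalyVariant]:
    """Emit corrupted second records for a fraction of the population.

    The corrupted subset has deterministic size ``round(fraction * n)``;
    each variant's cause is drawn from the configured mixture.
    """
    rng = random.Random(config.seed)
    k = round(config.fraction * len(persons))
    chosen = rng.sample(list(persons), k)
    variants: List[AnomalyVariant] = []
    for person in chosen:
        cause = _draw(rng, config.cause_mix)
        row = dict(person.row)
        if cause == "MARITAL_NAME":
            pool = NAME_POOLS[person.nationality]["surnames"]
            spouse = rng.choice([s for s in pool if s != row["last_name"]])
            row["last_name"] = spouse
        elif cause == "SPELLING":
            target = rng.choice(["first_name", "last_name"])
            row[target] = _typo(rng, row[target])
        elif cause == "LOCAL_ID":
            row["ssn"] = ""  # known to the domain only by demographics
        else:  # OTHER
            row["birth_date"] = _transpose_birth_date(rng, row["birth_date"])
        variants.append(AnomalyVariant(source=person, cause=cause, row=row))
    return variants


@dataclass
class DayResult:
    day: int
    ingest: "IngestSummary"
    anomalies_admitted: int
    duplicate_cases_opened: int
    delta_path: Optional[str] = None


def simulate_days(store, days: int, daily_volume: int,
                  population: PopulationConfig = None,
                  anomalies: AnomalyConfig = None,
                  secondary_domain: str = "hosp-a",
                  update_fraction: float = 0.1,
                  out_dir=None) -> List[DayResult]:
    """Drive the store through ``days`` daily cycles.

    Each day mixes fresh registry creations, updates of already-ingested
    people (an address change), and anomaly-bearing admissions pushed
    from a secondary domain; a surveillance scan closes the day. Delta
    CSVs are written per day when ``out_dir`` is given. Fully
    deterministic for fixed seeds.
    """
    import os

    from .delta import DeltaRecord, apply_delta, write_delta_file
    from .matching import process_identity_event
    from .vigilance import scan_potential_duplicates

    population = population or PopulationConfig(n=days * daily_volume)
    anomalies = anomalies or AnomalyConfig(fraction=0.0)
    if population.n < days * daily_volume:
        raise ValueError("population too small for days * daily_volume")
    rng = random.Random(population.seed ^ 0x5EED)

    if store.get_domain(secondary_domain).kind != "SECONDARY":
        raise ValueError(f"{secondary_domain!r} must be a SECONDARY domain")

    persons = generate_population(population)
    results: List[DayResult] = []
    ingested: List[Person] = []
    local_seq = 0
    for day in range(days):
        n_updates = int(update_fraction * daily_volume) if ingested else 0
        n_new = daily_volume - n_updates
        fresh = persons[len(ingested):len(ingested) + n_new]
        rows = [p.row for p in fresh]
        for person in rng.sample(ingested, min(n_updates, len(ingested))):
            row = dict(person.row)
            row["legal_address_line1"] = f"{rng.randrange(1, 200)} avenue de la Liberté"
            rows.append(row)

        delta_path = None
        if out_dir is not None:
            delta_path = os.path.join(str(out_dir), f"delta_day{day:03d}.csv")
            write_delta_file(delta_path, rows)
        records = [DeltaRecord(line_no=i + 2, row=row)
                   for i, row in enumerate(rows)]
        summary = apply_delta(store, records)
        ingested.extend(fresh)

        day_variants = inject_anomalies(
            fresh, AnomalyConfig(fraction=anomalies.fraction,
                                 cause_mix=anomalies.cause_mix,
                                 seed=anomalies.seed + day))
        for variant in day_variants:
            local_seq += 1
            process_identity_event(store, secondary_domain,
                                   f"SIM{local_seq:08d}", variant.row,
                                   event="CREATE")
        opened = scan_potential_duplicates(store)
        results.append(DayResult(day=day, ingest=summary,
                                 anomalies_admitted=len(day_variants),
                                 duplicate_cases_opened=len(opened),
                                 delta_path=delta_path))
    return results
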