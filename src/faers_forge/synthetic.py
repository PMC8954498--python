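"""Synthetic quarterly-extract generator with known ground truth.

Emits FAERS/LAERS-format "$"-delimited quarterly files (legacy layout
before 2012Q4, current layout after) whose every property is known by
construction, so the whole pipeline is testable without downloading real
extracts:

* field missingness at the database's documented marginal rates (gender
  null 11%, female 54%, US reporter 65%, country null 7%, event date null
  46%, age null 40%, therapy start date null 42%, indication null 12%);
* messy verbatim drug strings produced by weighted corruption operators
  (case changes, strength/dosage-form suffixes, manufacturer tags, echoed
  parentheses, reporter codes, brand and foreign trade names, typos) over
  a bundled mini-vocabulary, with the true ingredient recorded per row;
* cross-source duplicate reports that differ from their source case in at
  most one soft field and never in drugs or reactions, with duplicate
  groups recorded;
* planted drug–event association signals, either as exact contingency
  cells or as a target reporting odds ratio realized stochastically.

Two construction guarantees make ground truth exact.  In general mode the
(drug-set, reaction-set) hard key is unique per true case (rejection
sampling), so distinct cases can never satisfy the duplicate rule.  In
planted-signal mode many cases intentionally share hard keys, so instead
every true case receives a unique event date and a unique therapy start
date drawn from disjoint calendar ranges (and duplicate perturbations draw
from a third range): any two distinct cases then mismatch in at least two
soft fields.

The mini-vocabulary (~50 invented ingredients, brands, multi-ingredient
combinations, vaccines, non-primary-source ingredients and a granularity
exception, plus an IDD-style foreign trade-name table and an NDA table) is
large enough to exercise every branch of the mapping cascade and small
enough to eyeball.  All invented names are fictional; event and indication
terms are generic clinical phrases, not licensed terminology.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .report_io import (FaersDataset, QuarterExtract, _harmonize,
                        assemble_dataset, normalize_age)
from .vocab import Vocabulary, VocabularyEntry

# --------------------------------------------------------------- name universe

INGREDIENT_NAMES = [
    "ABEXOLID", "BARVUTINIB", "CALDEPRAN", "DOLVAXINE", "ELTRAZONE",
    "FAMUROLOL", "GALVEPTIN", "HIBRAFENE", "IXOLAMIDE", "JUVAPRIDE",
    "KELVORIN", "LOMEPRAZAN", "MIRVASTATIN", "NOLVAPARIN", "OXEMBRILIN",
    "PARVOXETINE", "QUELLIDONE", "RIVOZANTAN", "SOLMETINIB", "TREVOFLOXACIN",
    "ULMICYCLINE", "VANTOPRELIN", "WEXFORMIN", "XANOPRILAT", "YOLVEMAB",
    "ZEPHROLIMUS", "AMBRETHAZIDE", "BEXOTRIPTAN", "CRENOLUTIDE", "DORNIVUDINE",
    "ENFRAMYCIN", "FLUVOPERIDOL", "GRELDOPA", "HANTOPROST", "ILMOXICAM",
    "JORVICLOVIR", "KANDESIRAN", "LUMEFANTIDE", "MOXIBUPHEN", "NERVOCAINE",
    "OPRELVIMAB", "PILLOZOSIN", "QUINTAFUNGIN", "RALOMUSTINE", "SUVORETIDE",
    "TILMOCEPT", "UREXOLONE", "VILDAMANTINE", "WOLPERIZINE", "XIMERALFAN",
]

BRAND_TO_INGREDIENT = {
    "ABEXOR": "ABEXOLID", "CALDEPRA": "CALDEPRAN", "DOLVIX": "DOLVAXINE",
    "FAMUCOR": "FAMUROLOL", "HIBRAX": "HIBRAFENE", "KELVODEX": "KELVORIN",
    "MIRVATOR": "MIRVASTATIN", "PARVOXIL": "PARVOXETINE",
    "TREVOX": "TREVOFLOXACIN", "WEXIDE": "WEXFORMIN",
}

COMBO_PRODUCTS = {
    "ABEXOLID / CALDEPRAN": ("ABEXOLID", "CALDEPRAN"),
    "FAMUROLOL / WEXFORMIN": ("FAMUROLOL", "WEXFORMIN"),
    "GALVEPTIN / JUVAPRIDE": ("GALVEPTIN", "JUVAPRIDE"),
    "ELTRAZONE / IXOLAMIDE / KELVORIN": ("ELTRAZONE", "IXOLAMIDE", "KELVORIN"),
}

VACCINE_NAMES = ["NORVAXEL VACCINE", "TRIVOGEN COMBINED VACCINE"]
NON_PRIMARY_INGREDIENTS = ["PLUVASTONE", "QUORMETHASONE"]  # kept in MMSL only
GRANULARITY_ATOM = "DORNIVUDINE TRIPHOSPHATE"  # finer-grained non-primary form

#: invented foreign trade names (IDD-style) for the first 30 ingredients
IDD_FOREIGN_NAMES = {name[:5] + "IX": name for name in INGREDIENT_NAMES[:30]}

EVENT_TERMS = [
    "HEADACHE", "NAUSEA", "VOMITING", "DIZZINESS", "RASH", "PRURITUS",
    "FATIGUE", "INSOMNIA", "DIARRHOEA", "CONSTIPATION", "DYSPNOEA", "COUGH",
    "PYREXIA", "ARTHRALGIA", "MYALGIA", "BACK PAIN", "ABDOMINAL PAIN",
    "CHEST PAIN", "PALPITATIONS", "TACHYCARDIA", "BRADYCARDIA",
    "HYPERTENSION AGGRAVATED", "HYPOTENSION", "SYNCOPE", "TREMOR",
    "PARAESTHESIA", "SOMNOLENCE", "ANXIETY", "DEPRESSED MOOD", "CONFUSION",
    "MEMORY IMPAIRMENT", "VISION BLURRED", "TINNITUS", "VERTIGO", "DRY MOUTH",
    "DYSGEUSIA", "DECREASED APPETITE", "WEIGHT DECREASED", "WEIGHT INCREASED",
    "ALOPECIA", "HYPERHIDROSIS", "URTICARIA", "OEDEMA PERIPHERAL",
    "MUSCLE SPASMS", "RENAL IMPAIRMENT", "HEPATIC ENZYME INCREASED",
    "ANAEMIA", "THROMBOCYTOPENIA", "NEUTROPENIA", "EPISTAXIS",
    "GINGIVAL BLEEDING", "DEHYDRATION", "HYPERGLYCAEMIA", "HYPOGLYCAEMIA",
    "HYPOKALAEMIA", "FALL", "GAIT DISTURBANCE", "MALAISE", "CHILLS",
    "INFLUENZA LIKE ILLNESS",
]

INDICATION_TERMS = [
    "HYPERTENSION", "TYPE 2 DIABETES MELLITUS", "DEPRESSION",
    "ANXIETY DISORDER", "ASTHMA", "CHRONIC OBSTRUCTIVE PULMONARY DISEASE",
    "RHEUMATOID ARTHRITIS", "OSTEOARTHRITIS", "EPILEPSY",
    "MIGRAINE PROPHYLAXIS", "ATRIAL FIBRILLATION", "HEART FAILURE",
    "HYPERLIPIDAEMIA", "GASTROOESOPHAGEAL REFLUX", "PEPTIC ULCER",
    "PSORIASIS", "ECZEMA", "OSTEOPOROSIS", "BENIGN PROSTATIC HYPERPLASIA",
    "URINARY TRACT INFECTION", "PNEUMONIA", "INSOMNIA DISORDER",
    "CHRONIC PAIN", "THYROID DISORDER",
]

UNKNOWN_INDICATION_VARIANTS = [
    "Product used for unknown indication",
    "Drug use for unknown indication",
]

OUTCOME_CODES = ["DE", "LT", "HO", "DS", "CA", "OT"]
SOURCE_CODES = ["FGN", "HP", "CSM", "DT", "LIT"]
ROLE_CODES = ["PS", "SS", "C", "I"]
OTHER_COUNTRY_CODES = ["GB", "JP", "CA", "FR", "DE", "IT", "BR", "ES", "AU",
                       "NL", "CN", "CH", "SE", "IN", "CO", "TR", "BE", "AR", "PL"]
US_FORMS = ["US", "USA", "UNITED STATES OF AMERICA"]
COUNTRY_FULL_NAMES = {
    "GB": "UNITED KINGDOM", "JP": "JAPAN", "CA": "CANADA", "FR": "FRANCE",
    "DE": "GERMANY", "IT": "ITALY", "BR": "BRAZIL", "ES": "SPAIN",
    "AU": "AUSTRALIA", "NL": "THE NETHERLANDS", "CN": "CHINA",
    "CH": "SWITZERLAND", "SE": "SWEDEN", "IN": "INDIA", "CO": "COLOMBIA",
    "TR": "TURKEY", "BE": "BELGIUM", "AR": "ARGENTINA", "PL": "POLAND",
}

DEFAULT_CORRUPTION_WEIGHTS = {
    "identity": 0.30, "case": 0.10, "strength": 0.10, "form": 0.08,
    "echo": 0.06, "manufacturer": 0.05, "code": 0.05, "brand": 0.08,
    "idd": 0.08, "typo": 0.10,
}

STRENGTH_SUFFIXES = ["4MG", "10 MG", "250MG", "0.5 ML", "100 IU", "75 MCG"]
FORM_SUFFIXES = ["TABLETS", "CAPSULES", "I.V.", "ORAL SOLUTION",
                 "TABLETS/SUPPOSITORIES", "INJECTION"]
MANUFACTURER_TAGS = ["SANDOZ", "MYLAN", "TEVA", "HEXAL"]

_EVENT_BASE = date(2005, 1, 1)    # unique per-case event dates (signal mode)
_START_BASE = date(1950, 1, 1)    # unique per-case start dates (signal mode)
_PERTURB_BASE = date(1900, 1, 1)  # perturbed duplicate event dates


# ----------------------------------------------------------- mini vocabulary

@dataclass
class MiniVocab:
    """The bundled test vocabulary plus its companion lookup tables."""

    vocab: Vocabulary
    idd: dict[str, str]           # normalized foreign name -> rxaui
    nda_table: dict[str, str]     # NDA number -> rxaui
    ingredient_rxaui: dict[str, str]
    rxaui_name: dict[str, str]
    brand_rxaui: dict[str, str]
    combo_rxaui: dict[str, str]
    vaccine_rxauis: list[str]
    special_names: list[str]      # non-primary + granularity atoms


def build_mini_vocabulary() -> MiniVocab:
    """Construct the mini-vocabulary with every mapping branch represented."""
    entries: list[VocabularyEntry] = []
    relations: list[tuple[str, str, str]] = []
    ing_rxaui: dict[str, str] = {}
    for i, name in enumerate(INGREDIENT_NAMES):
        rxaui, rxcui = str(100001 + i), str(500001 + i)
        ing_rxaui[name] = rxaui
        entries.append(VocabularyEntry(rxaui, rxcui, name, "IN", "RXNORM"))
    brand_rxaui: dict[str, str] = {}
    for j, (brand, ing) in enumerate(sorted(BRAND_TO_INGREDIENT.items())):
        rxaui, rxcui = str(110001 + j), str(510001 + j)
        brand_rxaui[brand] = rxaui
        entries.append(VocabularyEntry(rxaui, rxcui, brand, "BN", "RXNORM"))
        relations.append((rxaui, "tradename_of", ing_rxaui[ing]))
    combo_rxaui: dict[str, str] = {}
    for k, (combo, parts) in enumerate(sorted(COMBO_PRODUCTS.items())):
        rxaui, rxcui = str(120001 + k), str(520001 + k)
        combo_rxaui[combo] = rxaui
        entries.append(VocabularyEntry(rxaui, rxcui, combo, "MIN", "RXNORM"))
        for part in parts:
            relations.append((rxaui, "has_ingredient", ing_rxaui[part]))
    vaccine_rxauis: list[str] = []
    for v, name in enumerate(VACCINE_NAMES):
        rxaui, rxcui = str(130001 + v), str(530001 + v)
        vaccine_rxauis.append(rxaui)
        src = "RXNORM" if v == 0 else "CVX"
        entries.append(VocabularyEntry(rxaui, rxcui, name, "SCD", src,
                                       exception="vaccine"))
    special = []
    for s, name in enumerate(NON_PRIMARY_INGREDIENTS):
        rxaui, rxcui = str(140001 + s), str(540001 + s)
        ing_rxaui[name] = rxaui
        special.append(name)
        entries.append(VocabularyEntry(rxaui, rxcui, name, "IN", "MMSL"))
    gran_rxaui = "150001"
    ing_rxaui[GRANULARITY_ATOM] = gran_rxaui
    special.append(GRANULARITY_ATOM)
    entries.append(VocabularyEntry(gran_rxaui, "550001", GRANULARITY_ATOM,
                                   "IN", "MTHSPL", exception="granularity"))
    vocab = Vocabulary(entries, relations)
    idd = {foreign: ing_rxaui[ing] for foreign, ing in IDD_FOREIGN_NAMES.items()}
    nda_table = {f"{20001 + i:06d}": ing_rxaui[name]
                 for i, name in enumerate(INGREDIENT_NAMES[:20])}
    rxaui_name = {e.rxaui: e.name for e in entries}
    return MiniVocab(vocab, idd, nda_table, ing_rxaui, rxaui_name,
                     brand_rxaui, combo_rxaui, vaccine_rxauis, special)


# ------------------------------------------------------------- configuration

@dataclass
class PlantedSignal:
    """A drug–event association to plant: exact cells or a target ROR."""

    ingredient: str
    pt: str
    cells: tuple[int, int, int, int] | None = None
    ror: float | None = None
    exposure: float = 0.15          # P(case gets drug X), stochastic mode
    baseline_event_rate: float = 0.08  # P(event Y | other drug)

    @property
    def q1(self) -> float:
        """P(event Y | drug X) giving the target odds ratio."""
        odds0 = self.baseline_event_rate / (1 - self.baseline_event_rate)
        odds1 = self.ror * odds0
        return odds1 / (1 + odds1)

    @property
    def true_ror(self) -> float | None:
        if self.cells is not None:
            a, b, c, d = self.cells
            return (a * d) / (b * c) if b and c else None
        return self.ror


@dataclass
class SynthConfig:
    """Generator configuration; defaults are the documented study conditions."""

    n_cases: int = 1000
    seed: int = 0
    quarters: tuple[str, ...] = ("2010Q1", "2016Q2", "2020Q3")
    gender_null_rate: float = 0.11
    female_rate: float = 0.54
    us_rate: float = 0.65
    country_null_rate: float = 0.07
    event_dt_null_rate: float = 0.46
    age_null_rate: float = 0.40
    start_dt_null_rate: float = 0.42
    indication_null_rate: float = 0.12
    correlate_missing_dates: bool = False  # 32% joint event/start missingness
    duplicate_rate: float = 0.0
    perturb_one_field: bool = True
    deleted_rate: float = 0.0
    name_corruption: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CORRUPTION_WEIGHTS))
    planted_signals: list[PlantedSignal] = field(default_factory=list)

    def validate(self) -> None:
        rates = {k: getattr(self, k) for k in (
            "gender_null_rate", "female_rate", "us_rate", "country_null_rate",
            "event_dt_null_rate", "age_null_rate", "start_dt_null_rate",
            "indication_null_rate", "duplicate_rate", "deleted_rate")}
        for k, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{k} must be in [0, 1], got {v}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.duplicate_rate > 0 and self.n_cases < 2:
            raise ValueError("duplicate_rate > 0 needs n_cases >= 2")
        if not self.quarters:
            raise ValueError("at least one quarter label required")
        if self.deleted_rate > 0 and not any(q >= "2019Q1" for q in self.quarters):
            raise ValueError("deleted_rate > 0 needs a quarter >= 2019Q1 "
                             "(deleted-case files only exist from 2019Q1)")
        if self.planted_signals:
            kinds = {s.cells is not None for s in self.planted_signals}
            if len(kinds) > 1:
                raise ValueError("cannot mix exact-cell and target-ROR signals")
            if kinds == {True}:
                used = 0
                for s in self.planted_signals:
                    a, b, c, d = s.cells
                    if min(a, b, c, d) < 0:
                        raise ValueError("cell targets must be non-negative")
                    if a > self.n_cases:
                        raise ValueError("target a exceeds n_cases")
                    if a + b + c + d != self.n_cases:
                        raise ValueError(
                            "exact cells must satisfy a+b+c+d == n_cases "
                            "(d counts every case without the drug and event)")
                    used += a + b + c
                if used > self.n_cases:
                    raise ValueError("planted signals exceed n_cases")
            names = [(s.ingredient, s.pt) for s in self.planted_signals]
            if len(set(names)) != len(names):
                raise ValueError("planted signals must be disjoint pairs")
            for s in self.planted_signals:
                if s.ingredient not in INGREDIENT_NAMES:
                    raise ValueError(f"unknown ingredient {s.ingredient!r}")
                if s.pt not in EVENT_TERMS:
                    raise ValueError(f"unknown event term {s.pt!r}")
                if s.cells is None and (s.ror is None or s.ror <= 0):
                    raise ValueError("signal needs cells or a positive ror")


@dataclass
class GroundTruthLedger:
    """Everything the generator knows that the pipeline must recover."""

    duplicate_groups: list[frozenset[str]]       # singletons included
    name_truth: pd.DataFrame                     # per drug row: truth + operator
    planted: list[PlantedSignal]
    deleted_caseids: set[str]

    def group_of(self) -> dict[str, frozenset[str]]:
        return {pid: g for g in self.duplicate_groups for pid in g}

    @property
    def true_pairs(self) -> set[tuple[str, str]]:
        """All unordered true duplicate pairs."""
        pairs = set()
        for g in self.duplicate_groups:
            for x in g:
                for y in g:
                    if x < y:
                        pairs.add((x, y))
        return pairs


# ---------------------------------------------------------------- corruption

def corrupt_drug_name(
    ingredient_name: str,
    rng: np.random.Generator,
    mini: MiniVocab,
    weights: dict[str, float] | None = None,
) -> tuple[str, str, bool]:
    """Produce one messy verbatim string for an ingredient.

    Returns ``(verbatim, operator, recoverable)`` — ``recoverable`` is True
    when the cascade (without manual overrides) is expected to resolve the
    string back to the true ingredient.
    """
    weights = weights or DEFAULT_CORRUPTION_WEIGHTS
    ops = sorted(weights)
    p = np.array([weights[o] for o in ops], dtype=float)
    p = p / p.sum()
    op = str(rng.choice(ops, p=p))
    name = ingredient_name
    if op == "brand":
        brands = [b for b, ing in BRAND_TO_INGREDIENT.items() if ing == name]
        if not brands:
            return name, "identity", True
        return brands[0], "brand", True
    if op == "idd":
        foreign = [f for f, ing in IDD_FOREIGN_NAMES.items() if ing == name]
        if not foreign:
            return name, "identity", True
        return foreign[0], "idd", True
    if op == "identity":
        return name, op, True
    if op == "case":
        return name.title() if rng.random() < 0.5 else name.lower(), op, True
    if op == "strength":
        return f"{name} {rng.choice(STRENGTH_SUFFIXES)}", op, True
    if op == "form":
        return f"{name} {rng.choice(FORM_SUFFIXES)}", op, True
    if op == "echo":
        return f"{name} ({name})", op, True
    if op == "manufacturer":
        return f"{name} ^{rng.choice(MANUFACTURER_TAGS)}^", op, True
    if op == "code":
        return f"{name} /{rng.integers(10 ** 7, 10 ** 8)}/", op, True
    # single-character typo; ensure it does not land on a known name
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for _ in range(8):
        pos = int(rng.integers(0, len(name)))
        repl = letters[int(rng.integers(0, 26))]
        if repl == name[pos]:
            continue
        cand = name[:pos] + repl + name[pos + 1:]
        if not mini.vocab.lookup(cand) and cand not in mini.idd:
            return cand, "typo", False
    return name + "X", "typo", False


# ----------------------------------------------------------- case construction

def _quarter_start(period: str) -> date:
    year, q = int(period[:4]), int(period[5])
    return date(year, 3 * (q - 1) + 1, 1)


def _fmt(d: date | None) -> str | None:
    return None if d is None else d.strftime("%Y%m%d")


def _sample_demo_fields(cfg: SynthConfig, rng: np.random.Generator) -> dict:
    u = rng.random()
    if u < cfg.gender_null_rate:
        gender = None
    elif u < cfg.gender_null_rate + cfg.female_rate:
        gender = "F"
    else:
        gender = "M"
    u = rng.random()
    if u < cfg.country_null_rate:
        country = None
    elif u < cfg.country_null_rate + cfg.us_rate:
        country = str(rng.choice(US_FORMS))
    else:
        code = str(rng.choice(OTHER_COUNTRY_CODES))
        country = code if rng.random() < 0.5 else COUNTRY_FULL_NAMES[code]
    if rng.random() < cfg.age_null_rate:
        age_val, age_cod = None, None
    else:
        unit = str(rng.choice(["YR", "MON", "DEC", "DY", "WK"],
                              p=[0.7, 0.1, 0.1, 0.05, 0.05]))
        rngs = {"YR": (1, 90), "MON": (1, 24), "DEC": (1, 9),
                "DY": (1, 300), "WK": (1, 100)}
        lo, hi = rngs[unit]
        age_val, age_cod = str(int(rng.integers(lo, hi + 1))), unit
    return {"gender": gender, "country": country,
            "age_val": age_val, "age_cod": age_cod}


def _sample_date_missing(cfg: SynthConfig, rng: np.random.Generator) -> tuple[bool, bool]:
    """(event_missing, start_missing), independent or jointly correlated."""
    if not cfg.correlate_missing_dates:
        return (rng.random() < cfg.event_dt_null_rate,
                rng.random() < cfg.start_dt_null_rate)
    p_both = 0.32
    p_event_only = cfg.event_dt_null_rate - p_both
    p_start_only = cfg.start_dt_null_rate - p_both
    u = rng.random()
    if u < p_both:
        return True, True
    if u < p_both + p_event_only:
        return True, False
    if u < p_both + p_event_only + p_start_only:
        return False, True
    return False, False


def _indication(cfg: SynthConfig, rng: np.random.Generator) -> str | None:
    u = rng.random()
    if u < cfg.indication_null_rate / 2:
        return None
    if u < cfg.indication_null_rate:
        return str(rng.choice(UNKNOWN_INDICATION_VARIANTS))
    return str(rng.choice(INDICATION_TERMS))


def plant_signal(
    n_cases: int,
    signals: list[PlantedSignal],
    rng: np.random.Generator,
    filler_drugs: list[str],
    filler_events: list[str],
) -> list[tuple[str, str]]:
    """Per-case (drug, event) assignments realizing the planted signals.

    Exact-cell signals are allocated deterministically over disjoint case
    ranges (the remaining cases are filler/filler, which is what makes the
    d cell exact); target-ROR signals sample exposure and conditional event
    occurrence per case.
    """
    if not filler_drugs or not filler_events:
        raise ValueError("filler pools must be non-empty")
    exact = signals[0].cells is not None
    if exact:
        assignments: list[tuple[str, str]] = []
        for s in signals:
            a, b, c, _ = s.cells
            assignments += [(s.ingredient, s.pt)] * a
            assignments += [(str(rng.choice(filler_drugs)), s.pt)] * b
            assignments += [(s.ingredient, str(rng.choice(filler_events)))] * c
        if len(assignments) > n_cases:
            raise ValueError("planted signals exceed n_cases")
        while len(assignments) < n_cases:
            assignments.append((str(rng.choice(filler_drugs)),
                                str(rng.choice(filler_events))))
        return assignments
    if len(signals) != 1:
        raise ValueError("stochastic mode supports one signal at a time")
    s = signals[0]
    assignments = []
    for _ in range(n_cases):
        exposed = rng.random() < s.exposure
        drug = s.ingredient if exposed else str(rng.choice(filler_drugs))
        q = s.q1 if exposed else s.baseline_event_rate
        event = s.pt if rng.random() < q else str(rng.choice(filler_events))
        assignments.append((drug, event))
    return assignments


def _build_cases(cfg: SynthConfig, mini: MiniVocab,
                 rng: np.random.Generator) -> list[dict]:
    """All true (non-duplicate) cases as internal record dicts."""
    n = cfg.n_cases
    quarters = sorted(cfg.quarters)
    signal_mode = bool(cfg.planted_signals)
    cases: list[dict] = []

    if signal_mode:
        planted_drugs = {s.ingredient for s in cfg.planted_signals}
        planted_events = {s.pt for s in cfg.planted_signals}
        filler_drugs = [x for x in INGREDIENT_NAMES if x not in planted_drugs]
        filler_events = [x for x in EVENT_TERMS if x not in planted_events]
        assignments = plant_signal(n, cfg.planted_signals, rng,
                                   filler_drugs, filler_events)
    used_keys: set[tuple[frozenset, frozenset]] = set()

    for i in range(n):
        period = quarters[int(rng.integers(0, len(quarters)))]
        qstart = _quarter_start(period)
        fda = qstart + timedelta(days=int(rng.integers(0, 85)))
        demo = _sample_demo_fields(cfg, rng)
        event_missing, start_missing = _sample_date_missing(cfg, rng)

        if signal_mode:
            drug_name, pt = assignments[i]
            drugs = [{"verbatim": drug_name,
                      "truths": (mini.ingredient_rxaui[drug_name],),
                      "operator": "identity", "recoverable": True,
                      "nda": None}]
            reactions = [pt]
            event = _EVENT_BASE + timedelta(days=i)      # unique per case
            start = _START_BASE + timedelta(days=i)      # unique per case
            event_s, start_s = _fmt(event), _fmt(start)
        else:
            # unique (drug set, reaction set) hard key per true case
            for _attempt in range(1000):
                k = int(rng.choice([1, 2, 3], p=[0.6, 0.3, 0.1]))
                slots: list[tuple[str, tuple[str, ...]]] = []
                chosen: set[str] = set()
                while len(slots) < k:
                    u = rng.random()
                    if u < 0.06:
                        combo = str(rng.choice(sorted(COMBO_PRODUCTS)))
                        truths = tuple(mini.ingredient_rxaui[p]
                                       for p in COMBO_PRODUCTS[combo])
                        key = combo
                    elif u < 0.08:
                        v = int(rng.integers(0, len(VACCINE_NAMES)))
                        key = VACCINE_NAMES[v]
                        truths = (mini.vaccine_rxauis[v],)
                    elif u < 0.11:
                        key = str(rng.choice(mini.special_names))
                        truths = (mini.ingredient_rxaui[key],)
                    else:
                        key = str(rng.choice(INGREDIENT_NAMES))
                        truths = (mini.ingredient_rxaui[key],)
                    if key in chosen:
                        continue
                    chosen.add(key)
                    slots.append((key, truths))
                m = int(rng.choice([1, 2], p=[0.7, 0.3]))
                pts = [str(x) for x in
                       rng.choice(EVENT_TERMS, size=m, replace=False)]
                hard = (frozenset(t for _, ts in slots for t in ts),
                        frozenset(pts))
                if hard not in used_keys:
                    used_keys.add(hard)
                    break
            else:  # pragma: no cover - space far larger than any sane n
                raise RuntimeError("could not find an unused hard key")
            drugs = []
            for key, truths in slots:
                if key in COMBO_PRODUCTS or key in VACCINE_NAMES:
                    verbatim = key if rng.random() < 0.7 else key.title()
                    op, rec = ("identity", True) if verbatim == key else ("case", True)
                else:
                    verbatim, op, rec = corrupt_drug_name(
                        key, rng, mini, cfg.name_corruption)
                nda = None
                if (op == "identity" and len(truths) == 1
                        and key not in VACCINE_NAMES and rng.random() < 0.10):
                    for num, rx in mini.nda_table.items():
                        if rx == truths[0]:
                            nda = num
                            break
                drugs.append({"verbatim": verbatim, "truths": truths,
                              "operator": op, "recoverable": rec, "nda": nda})
            reactions = pts
            event = fda - timedelta(days=int(rng.integers(1, 400)))
            start = event - timedelta(days=int(rng.integers(0, 60)))
            event_s = None if event_missing else _fmt(event)
            start_s = None if start_missing else _fmt(start)

        case = {
            "pid": str(4000000 + i),
            "caseid": str(8000000 + i),
            "period": period,
            "i_f": "I" if rng.random() < 0.8 else "F",
            "fda": _fmt(fda),
            "event": event_s,
            **demo,
            "drugs": [],
            "reactions": list(reactions),
            "outc": [str(rng.choice(OUTCOME_CODES))] if rng.random() < 0.75 else [],
            "rpsr": [str(rng.choice(SOURCE_CODES))] if rng.random() < 0.5 else [],
        }
        for seq, d in enumerate(drugs, start=1):
            case["drugs"].append({
                "seq": str(seq),
                "verbatim": d["verbatim"],
                "truths": d["truths"],
                "operator": d["operator"],
                "recoverable": d["recoverable"],
                "nda": d["nda"],
                "role": str(rng.choice(ROLE_CODES)),
                "start": start_s,
                "indi": _indication(cfg, rng),
            })
        cases.append(case)
    return cases


def _perturb_duplicate(dup: dict, j: int, rng: np.random.Generator) -> None:
    """Change at most one non-null soft field of a duplicate, in place."""
    candidates = ["gender", "age", "country", "event"]
    rng.shuffle(candidates)
    for fieldname in candidates:
        if fieldname == "gender" and dup["gender"] in ("F", "M"):
            dup["gender"] = "M" if dup["gender"] == "F" else "F"
            return
        if fieldname == "age" and dup["age_val"] is not None:
            years = normalize_age(dup["age_val"], dup["age_cod"])
            if years is None:
                continue
            dup["age_val"] = str(int(round(years + 5)))
            dup["age_cod"] = "YR"
            return
        if fieldname == "country" and dup["country"] is not None:
            from .report_io import normalize_country
            current = normalize_country(dup["country"])
            pool = [c for c in OTHER_COUNTRY_CODES + ["US"] if c != current]
            dup["country"] = str(rng.choice(pool))
            return
        if fieldname == "event" and dup["event"] is not None:
            dup["event"] = _fmt(_PERTURB_BASE + timedelta(days=j))
            return


def _inject_duplicates(cases: list[dict], cfg: SynthConfig,
                       rng: np.random.Generator) -> list[frozenset[str]]:
    """Re-emit a fraction of cases as cross-source duplicates."""
    n = len(cases)
    n_dup = int(round(cfg.duplicate_rate * n))
    groups: dict[str, set[str]] = {c["pid"]: {c["pid"]} for c in cases}
    if n_dup:
        quarters = sorted(cfg.quarters)
        sources = rng.choice(n, size=n_dup, replace=False)
        for j, si in enumerate(sources):
            src = cases[int(si)]
            dup = {k: (list(v) if isinstance(v, list) else v)
                   for k, v in src.items()}
            dup["drugs"] = [dict(d) for d in src["drugs"]]
            dup["pid"] = str(4000000 + n + j)
            dup["caseid"] = str(8000000 + n + j)
            later = [q for q in quarters if q >= src["period"]]
            dup["period"] = str(rng.choice(later)) if later else src["period"]
            fda = pd.to_datetime(src["fda"], format="%Y%m%d").date()
            dup["fda"] = _fmt(fda + timedelta(days=int(rng.integers(1, 30))))
            dup["i_f"] = "F"
            if cfg.perturb_one_field:
                _perturb_duplicate(dup, j, rng)
            groups[src["pid"]].add(dup["pid"])
            cases.append(dup)
    return [frozenset(g) for g in groups.values()]


def _select_deleted(cases: list[dict], groups: list[frozenset[str]],
                    cfg: SynthConfig, rng: np.random.Generator) -> set[str]:
    """Caseids destined for the deleted-case lists (singleton cases only)."""
    n_del = int(round(cfg.deleted_rate * cfg.n_cases))
    if not n_del:
        return set()
    singleton_pids = {next(iter(g)) for g in groups if len(g) == 1}
    eligible = [c for c in cases if c["pid"] in singleton_pids]
    chosen = rng.choice(len(eligible), size=min(n_del, len(eligible)),
                        replace=False)
    return {eligible[int(i)]["caseid"] for i in chosen}


# ----------------------------------------------------------------- rendering

def _is_legacy(period: str) -> bool:
    return period < "2012Q4"


def _quarter_raw_tables(cases: list[dict], period: str) -> dict[str, tuple[list[str], list[list[str]]]]:
    """Raw (header, rows) per table kind for one quarter, both eras."""
    legacy = _is_legacy(period)
    sub = [c for c in cases if c["period"] == period]

    def s(v) -> str:
        return "" if v is None else str(v)

    if legacy:
        demo_h = ["ISR", "CASE", "i_f_cod", "event_dt", "fda_dt", "age",
                  "age_cod", "gndr_cod", "reporter_country"]
        drug_h = ["ISR", "drug_seq", "role_cod", "drugname", "nda_num"]
    else:
        demo_h = ["primaryid", "caseid", "caseversion", "i_f_code", "event_dt",
                  "fda_dt", "age", "age_cod", "sex", "reporter_country"]
        drug_h = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai",
                  "nda_num"]
    out: dict[str, tuple[list[str], list[list[str]]]] = {
        "demo": (demo_h, []), "drug": (drug_h, []),
        "reac": (["primaryid" if not legacy else "ISR", "pt"], []),
        "indi": (["primaryid" if not legacy else "ISR", "indi_drug_seq",
                  "indi_pt"], []),
        "ther": (["primaryid" if not legacy else "ISR", "dsg_drug_seq",
                  "start_dt", "end_dt", "dur", "dur_cod"], []),
        "outc": (["primaryid" if not legacy else "ISR", "outc_cod"], []),
        "rpsr": (["primaryid" if not legacy else "ISR", "rpsr_cod"], []),
    }
    for c in sub:
        pid = c["pid"]
        if legacy:
            out["demo"][1].append([pid, c["caseid"], c["i_f"], s(c["event"]),
                                   s(c["fda"]), s(c["age_val"]), s(c["age_cod"]),
                                   s(c["gender"]), s(c["country"])])
        else:
            out["demo"][1].append([pid, c["caseid"], "1", c["i_f"],
                                   s(c["event"]), s(c["fda"]), s(c["age_val"]),
                                   s(c["age_cod"]), s(c["gender"]),
                                   s(c["country"])])
        for d in c["drugs"]:
            prod_ai = "\\".join(
                INGREDIENT_NAMES[int(t) - 100001] if t.isdigit()
                and 100001 <= int(t) < 100001 + len(INGREDIENT_NAMES) else ""
                for t in d["truths"]) if not legacy else None
            if prod_ai is not None and prod_ai.strip("\\") == "":
                prod_ai = None
            row = [pid, d["seq"], d["role"], d["verbatim"]]
            if not legacy:
                row.append(s(prod_ai))
            row.append(s(d["nda"]))
            out["drug"][1].append(row)
            out["indi"][1].append([pid, d["seq"], s(d["indi"])])
            if d["start"] is not None:
                end = pd.to_datetime(d["start"], format="%Y%m%d").date() \
                    + timedelta(days=14)
                out["ther"][1].append([pid, d["seq"], d["start"], _fmt(end),
                                       "14", "DAY"])
            else:
                out["ther"][1].append([pid, d["seq"], "", "", "", ""])
        for pt in c["reactions"]:
            out["reac"][1].append([pid, pt])
        for code in c["outc"]:
            out["outc"][1].append([pid, code])
        for code in c["rpsr"]:
            out["rpsr"][1].append([pid, code])
    return out


def _make_ledger(cases: list[dict], groups: list[frozenset[str]],
                 cfg: SynthConfig, deleted: set[str]) -> GroundTruthLedger:
    rows = [(c["pid"], d["seq"], d["verbatim"], d["truths"], d["operator"],
             d["recoverable"])
            for c in cases for d in c["drugs"]]
    truth = pd.DataFrame(rows, columns=[
        "primaryid", "drug_seq", "verbatim", "truth_rxauis", "operator",
        "recoverable"])
    return GroundTruthLedger(duplicate_groups=groups, name_truth=truth,
                             planted=list(cfg.planted_signals),
                             deleted_caseids=deleted)


def _simulate(cfg: SynthConfig, mini: MiniVocab | None = None
              ) -> tuple[list[dict], GroundTruthLedger, MiniVocab]:
    cfg.validate()
    mini = mini or build_mini_vocabulary()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 20220223]))
    cases = _build_cases(cfg, mini, rng)
    groups = _inject_duplicates(cases, cfg, rng)
    deleted = _select_deleted(cases, groups, cfg, rng)
    ledger = _make_ledger(cases, groups, cfg, deleted)
    return cases, ledger, mini


def generate_dataset(cfg: SynthConfig, mini: MiniVocab | None = None
                     ) -> tuple[FaersDataset, GroundTruthLedger, MiniVocab]:
    """Generate directly into a combined in-memory dataset (no file IO).

    Produces the same harmonized tables as writing the quarterly files and
    re-parsing them (asserted by test); preferred for replicated runs.
    """
    cases, ledger, mini = _simulate(cfg, mini)
    per_quarter = []
    for period in sorted(cfg.quarters):
        raw = _quarter_raw_tables(cases, period)
        tables = {}
        for kind, (header, rows) in raw.items():
            df = pd.DataFrame(rows, columns=[h.lower() for h in header],
                              dtype=object).replace("", pd.NA)
            tables[kind] = _harmonize(df, kind, period)
        per_quarter.append(tables)
    ds = assemble_dataset(per_quarter, [ledger.deleted_caseids], [])
    return ds, ledger, mini


def generate_extracts(cfg: SynthConfig, outdir: str | Path,
                      mini: MiniVocab | None = None, write_vocab: bool = True
                      ) -> tuple[list[QuarterExtract], GroundTruthLedger]:
    """Write quarterly extract files (plus companion tables) to ``outdir``."""
    cases, ledger, mini = _simulate(cfg, mini)
    outdir = Path(outdir)
    extracts = []
    for period in sorted(cfg.quarters):
        qdir = outdir / period
        qdir.mkdir(parents=True, exist_ok=True)
        raw = _quarter_raw_tables(cases, period)
        paths: dict[str, Path] = {}
        for kind, (header, rows) in raw.items():
            path = qdir / f"{kind.upper()}{period}.txt"
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("$".join(header) + "\n")
                for row in rows:
                    fh.write("$".join(row) + "\n")
            paths[kind] = path
        if period >= "2019Q1":
            # deleted lists may name any historical caseid; removal is
            # idempotent, so each eligible quarter carries the full set
            dpath = qdir / f"DELETED{period}.txt"
            with open(dpath, "w", encoding="utf-8") as fh:
                fh.write("caseid\n")
                for cid in sorted(ledger.deleted_caseids):
                    fh.write(cid + "\n")
            paths["deleted"] = dpath
        extracts.append(QuarterExtract(period=period, paths=paths))
    if write_vocab:
        vdir = outdir / "vocab"
        mini.vocab.to_rrf(vdir)
        from .standardize import write_two_column_table
        write_two_column_table(mini.idd, vdir / "idd.tsv", "foreign_name")
        with open(vdir / "nda.tsv", "w", encoding="utf-8") as fh:
            fh.write("nda_num\trxaui\n")
            for num in sorted(mini.nda_table):
                fh.write(f"{num}\t{mini.nda_table[num]}\n")
        import json
        with open(vdir / "exceptions.json", "w", encoding="utf-8") as fh:
            json.dump(mini.vocab.exception_map(), fh, indent=0, sort_keys=True)
    return extracts, ledger


# ------------------------------------------------------------- measurement

def measure_missingness(ds: FaersDataset) -> dict[str, float]:
    """Empirical marginal null rates, measured as the database documents them."""
    demo = ds.demo
    n = len(demo)
    start_by_case = ds.ther.groupby("primaryid")["start_dt"] \
        .apply(lambda s: s.notna().any())
    case_ids = set(demo["primaryid"])
    start_present = sum(bool(start_by_case.get(pid, False)) for pid in case_ids)
    indi = ds.indi
    ipt = indi["indi_pt"].astype("string").str.strip().str.casefold()
    from .dedup import UNKNOWN_INDICATION_PHRASES
    indi_null = (ipt.isna() | ipt.isin(UNKNOWN_INDICATION_PHRASES)).mean()
    return {
        "gender_null": float(demo["gender"].isna().mean()),
        "female": float((demo["gender"] == "F").sum() / n) if n else float("nan"),
        "us_share": float((demo["country_code"] == "US").sum() / n) if n else float("nan"),
        "country_null": float(demo["country_code"].isna().mean()),
        "event_dt_null": float(demo["event_dt"].isna().mean()),
        "age_null": float(demo["age_years"].isna().mean()),
        "start_dt_null": float(1 - start_present / n) if n else float("nan"),
        "indication_null": float(indi_null) if len(indi) else float("nan"),
    }


def config_from_dict(d: dict) -> SynthConfig:
    """Build a SynthConfig from a plain dict (JSON/YAML config files)."""
    d = dict(d)
    signals = [PlantedSignal(**s) if not isinstance(s, PlantedSignal) else s
               for s in d.pop("planted_signals", [])]
    for s in signals:
        if s.cells is not None:
            s.cells = tuple(s.cells)
    quarters = tuple(d.pop("quarters", SynthConfig.quarters))
    fields = {f.name for f in dataclasses.fields(SynthConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SynthConfig(quarters=quarters, planted_signals=signals, **d)
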