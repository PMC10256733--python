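"""Questionnaire-to-quantitative encodings for dietary phenotypes.

UK-Biobank-style touchscreen food-frequency answers are converted to a
single quantitative scale before GWAS: daily counts become weekly counts
(3 cups/day -> 21 cups/week), semi-quantitative categories map onto
0 / 3 / 5.5 / 7 servings per week, and hot-drink temperature maps onto an
arbitrary 3 / 2 / 1 scale.  Respondents who chose not to answer, were not
sure, or (for temperature) do not drink hot drinks are excluded rather
than coded.

All functions are pure and total over the declared enums; ``EXCLUDE`` is
the single non-numeric outcome.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

from .errors import ValidationError


class _Exclude:
    """Sentinel marking a respondent excluded from the analysis."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "EXCLUDE"

    def __bool__(self) -> bool:
        return False


EXCLUDE = _Exclude()

DAYS_PER_WEEK = 7.0


class FrequencyKind(str, Enum):
    PER_DAY_COUNT = "per_day_count"
    PER_WEEK_COUNT = "per_week_count"
    SEMI_QUANTITATIVE_CATEGORY = "semi_quantitative_category"
    NO_ANSWER = "no_answer"
    NOT_SURE = "not_sure"


class IntakeCategory(str, Enum):
    NEVER = "never"
    TWO_FOUR_PER_WEEK = "two_four_per_week"
    FIVE_SIX_PER_WEEK = "five_six_per_week"
    ONCE_OR_MORE_PER_DAY = "once_or_more_per_day"


#: weekly-serving values for the four semi-quantitative categories
CATEGORY_WEEKLY: Mapping[IntakeCategory, float] = {
    IntakeCategory.NEVER: 0.0,
    IntakeCategory.TWO_FOUR_PER_WEEK: 3.0,
    IntakeCategory.FIVE_SIX_PER_WEEK: 5.5,
    IntakeCategory.ONCE_OR_MORE_PER_DAY: 7.0,
}


class DrinkTemperature(str, Enum):
    VERY_HOT = "very_hot"
    HOT = "hot"
    WARM = "warm"
    NO_HOT_DRINKS = "no_hot_drinks"


TEMPERATURE_SCALE: Mapping[DrinkTemperature, int] = {
    DrinkTemperature.VERY_HOT: 3,
    DrinkTemperature.HOT: 2,
    DrinkTemperature.WARM: 1,
}


@dataclass(frozen=True)
class FrequencyResponse:
    kind: FrequencyKind
    value: float | str | None = None


@dataclass(frozen=True)
class TemperatureResponse:
    category: DrinkTemperature


def weekly_consumption(response: FrequencyResponse):
    """Convert a frequency response to weekly servings, or ``EXCLUDE``.

    Counts per day are multiplied by 7; counts per week pass through;
    the four semi-quantitative categories map to 0, 3, 5.5 and 7.
    """
    kind = FrequencyKind(response.kind)
    if kind in (FrequencyKind.NO_ANSWER, FrequencyKind.NOT_SURE):
        return EXCLUDE
    if kind is FrequencyKind.SEMI_QUANTITATIVE_CATEGORY:
        try:
            category = IntakeCategory(response.value)
        except ValueError:
            raise ValidationError(f"unknown intake category {response.value!r}") from None
        return CATEGORY_WEEKLY[category]
    try:
        count = float(response.value)
    except (TypeError, ValueError):
        raise ValidationError(f"non-numeric count {response.value!r}") from None
    if count < 0:
        raise ValidationError(f"negative consumption count {count}")
    if kind is FrequencyKind.PER_DAY_COUNT:
        return DAYS_PER_WEEK * count
    return count


def temperature_scale(response: TemperatureResponse | DrinkTemperature):
    """Map a drink-temperature answer to the 3/2/1 scale, or ``EXCLUDE``
    for respondents who do not consume hot drinks."""
    category = response.category if isinstance(response, TemperatureResponse) else response
    try:
        category = DrinkTemperature(category)
    except ValueError:
        raise ValidationError(f"unknown temperature category {category!r}") from None
    if category is DrinkTemperature.NO_HOT_DRINKS:
        return EXCLUDE
    return TEMPERATURE_SCALE[category]


def parse_frequency_response(text: str) -> FrequencyResponse:
    """Parse a compact response string as used in two-column TSV input.

    Accepted forms: ``"3/day"``, ``"2.5/week"``, any
    :class:`IntakeCategory` name, ``"no_answer"``, ``"not_sure"``.
    """
    token = text.strip().lower()
    if token in (FrequencyKind.NO_ANSWER.value, FrequencyKind.NOT_SURE.value):
        return FrequencyResponse(FrequencyKind(token))
    if token in {c.value for c in IntakeCategory}:
        return FrequencyResponse(FrequencyKind.SEMI_QUANTITATIVE_CATEGORY, token)
    if "/" in token:
        count_text, _, unit = token.partition("/")
        try:
            count = float(count_text)
        except ValueError:
            raise ValidationError(f"unparseable response {text!r}") from None
        if unit == "day":
            return FrequencyResponse(FrequencyKind.PER_DAY_COUNT, count)
        if unit == "week":
            return FrequencyResponse(FrequencyKind.PER_WEEK_COUNT, count)
    raise ValidationError(f"unparseable response {text!r}")


def encode_frequency_table(rows: Iterable[tuple[str, str]]) -> list[tuple[str, float | None]]:
    """Encode (respondent_id, response-string) pairs; excluded respondents
    get ``None``."""
    encoded = []
    for respondent, text in rows:
        value = weekly_consumption(parse_frequency_response(text))
        encoded.append((respondent, None if value is EXCLUDE else float(value)))
    return encoded


# --- filter predicates for upstream stratifications --------------------
# The coffee-type stratification and the non-dairy milk exclusion happen at
# GWAS time upstream; here they exist only as predicates on tagged records.

NON_DAIRY_MILK = frozenset({"soy", "oat", "almond", "rice", "other_non_dairy"})


def coffee_type_filter(records: Iterable[Mapping], coffee_type: str) -> list[Mapping]:
    """Keep records whose ``coffee_type`` tag equals ``coffee_type``;
    records without a stated type are excluded."""
    return [r for r in records if r.get("coffee_type") == coffee_type]


def exclude_non_dairy(records: Iterable[Mapping]) -> list[Mapping]:
    """Drop records whose ``milk_type`` tag is a non-dairy milk."""
    return [r for r in records if r.get("milk_type") not in NON_DAIRY_MILK]
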