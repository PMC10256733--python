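"""Questionnaire encodings used upstream of the diet GWASs.

Frequency answers become weekly counts (3 cups/day -> 21/week; the
semi-quantitative categories map to 0, 3, 5.5, 7) and hot-drink
temperature becomes a 3/2/1 scale; non-answers are excluded.
"""

from mrdiet import (
    DrinkTemperature,
    TemperatureResponse,
    parse_frequency_response,
    temperature_scale,
    weekly_consumption,
)

for answer in ["3/day", "2/week", "never", "two_four_per_week",
               "five_six_per_week", "once_or_more_per_day", "not_sure"]:
    value = weekly_consumption(parse_frequency_response(answer))
    print(f"{answer:>22} -> {value}")

for temp in DrinkTemperature:
    print(f"{temp.value:>22} -> {temperature_scale(TemperatureResponse(temp))}")
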