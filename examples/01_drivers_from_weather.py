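"""Compute seasonal growth drivers from daily weather.

Simulates one April-October season for a dry continental climate, then
accumulates the two drivers: thermal time (growing degree days above 10 degC,
daily mean clamped at 40 degC) and FAO-56 Penman-Monteith reference
evapotranspiration. The relative forms divide each running sum by its season
total, mapping the season onto [0, 1] for the growth models.
"""

import cotgrow as cg

weather = cg.generate_weather(cg.ARID_CONTINENTAL, year=2020, seed=1)
cgdd = cg.cumulative_gdd(weather)
ceto = cg.cumulative_eto(weather)

print(f"season: {weather[0].date} .. {weather[-1].date} ({len(weather)} days)")
print(f"thermal time total:        {cgdd.season_total:8.1f} degC*d")
print(f"reference ET total:        {ceto.season_total:8.1f} mm")
mid = len(weather) // 2
print(f"mid-season relative CGDD:  {cgdd.relative[mid]:8.3f}")
print(f"mid-season relative CETo:  {ceto.relative[mid]:8.3f}")

# Roughly half of each driver accumulates by mid-season; the relative values
# are the x-axis on which all growth curves below are expressed.
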