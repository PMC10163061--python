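"""Closed-form yield / irrigation optimum and water use efficiency.

The yield response to maximum leaf area index and the LAI_max response to
seasonal irrigation are concave quadratics; their vertices and roots give
the yield-optimal LAI_max, the water-economical irrigation reaching it, and
the irrigation water use efficiency (IWUE = yield / irrigation) there. IWUE
is reported in two labelled modes: the published quartic-over-W expression
with its coefficients verbatim, and the exact composition of the two
quadratics (which differ because the published cubic coefficient is
rounded).
"""

import cotgrow as cg

rep = cg.optimal_irrigation_report()
print(f"yield-optimal LAI_max:      {rep['laimax_optimal']:.3f} cm2/cm2")
print(f"maximum seed-cotton yield:  {rep['yield_max_kg_ha']:.1f} kg/ha")
print(f"required irrigation:        {rep['w_required_mm']:.3f} mm ({rep['branch']} branch)")
print(f"LAI_max saturates at:       {rep['w_vertex_mm']:.3f} mm")
print(f"IWUE, published expression: {rep['iwue_as_printed']:.3f} kg/(ha*mm)")
print(f"IWUE, exact composition:    {rep['iwue_composed']:.3f} kg/(ha*mm)")

# The required irrigation sits below the saturation point: the last
# millimetres toward LAI_max saturation buy no extra yield.
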