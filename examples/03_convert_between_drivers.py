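"""Convert growth-model parameters between driver bases through the link.

Within a region, relative evapotranspiration is nearly an affine function of
relative thermal time, R_CETo = m*R_CGDD + n. Under that link a logistic
exponent converts in closed form, so an evapotranspiration-driven model can
be obtained from a thermal-time fit without meteorological refitting. Here
the link back-solved from the pooled published height row converts the
pooled LAI model; the result matches the published calculated coefficients.
"""

import cotgrow as cg

# link implied by the pooled height parameter pair
link = cg.link_registry()["Total"]
print(f"pooled driver link: m={link.m:.4f}, n={link.n:.4f}  ({link.provenance})")

lai = cg.all_region_preset("LAI", "CGDD")
d, e, f = cg.convert_quadratic_params(lai.intercept, lai.slope, lai.curvature, link)
print(f"thermal-time LAI exponent:   a={lai.intercept}, b={lai.slope}, c={lai.curvature}")
print(f"converted CETo exponent:     d={d:.3f}, e={e:.3f}, f={f:.3f}")

published = cg.regional_table("LAI")["Total"]["ceto_cal"]
print(
    "published calculated values: d={intercept}, e={slope}, f={curvature}".format(
        **published
    )
)

# A link can equally be fitted from simulated paired seasonal drivers:
season = cg.generate_region_set(
    [cg.ARID_CONTINENTAL, cg.WARM_TEMPERATE_MONSOON], seed=1
)["arid-continental"]
fitted = cg.fit_link_linear(season.cgdd.relative, season.ceto.relative)
print(
    f"link fitted from one simulated season: m={fitted.m:.4f}, n={fitted.n:.4f}, "
    f"R^2={fitted.r_squared:.4f}"
)
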