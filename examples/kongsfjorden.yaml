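# Example run configuration for a Kongsfjorden-style summer analysis.
# Water-mass envelope bounds follow Cottier et al. (2005); verify them
# against your own classification scheme before use.

watermasses:
  - {name: AW,  tmin: 3.0, smin: 34.9, priority: 1}
  - {name: TAW, tmin: 1.0, tmax: 3.0, smin: 34.7, priority: 2}
  - {name: IW,  tmin: 1.0, smin: 34.0, smax: 34.65, priority: 3}
  - {name: SW,  tmin: 1.0, smax: 34.0, priority: 4}

endmembers:
  fresh_salinity: 0.0          # glacier melt assumed salt-free
  fresh:                       # µmol kg⁻¹ (glacial-river means)
    ammonium: 1.44
    nitrate_nitrite: 2.00
    phosphate: 0.064
    silicic_acid: 9.77
    dic: regression            # per-year Y-intercept of DIC ~ salinity in SW

flushing:
  method: fixed
  ft_days: 13.0                # mean of hydrodynamic-model range
  # method: loicz              # alternative salt-balance estimate:
  # volume: 2.0e10             # m³
  # q_freshwater: 100          # m³ s⁻¹
  # s_ocean: 35.0
  # s_fjord: 34.65

analysis:
  depth_max: 100.0             # m; 50 and 150 are the sensitivity presets
  density: 1000.0              # kg m⁻³ for depth integration
  area_km2: 231.5
  alpha: 0.05
  tracers: [nitrate_nitrite, dic]
  pairs: [AWs_vs_IW, AWs_vs_SW, AWs_vs_AWf]
  exclusions: []               # e.g. [[2020, AWs_vs_SW]] to drop outliers

budget:
  river_conc_umol_L: 2.0       # nitrate in glacial rivers
  din_conc_umol_L: 2.5         # DIN at the fjord mouth
  constants:                   # tonnes N d⁻¹; positive = into the water column
    sediment denitrification: {category: sediment, value: -3.0}
    bird consumption: {category: biological, value: -0.13}

out_dir: results
seed: 0
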