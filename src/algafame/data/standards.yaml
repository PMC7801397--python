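# Built-in biodiesel specification registry: cetane-number minimum and
# cold-filter-plugging-point window per national/regional standard.
# cfpp_min / cfpp_max omitted or null => unconstrained.
standards:
  - code: "EN 14214: 2008"
    region: "European"
    cn_min: 51
    cfpp_min: -18
    cfpp_max: 0
  - code: "ASTM D6751"
    region: "United States"
    cn_min: 47
    cfpp_min: -18
    cfpp_max: 3
  - code: "RANP/2008"
    region: "Brazil"
    cn_min: 47
    cfpp_min: null
    cfpp_max: null
  - code: "SIRIM MS 123: 2005"
    region: "Malaysia"
    cn_min: 51
    cfpp_min: null
    cfpp_max: 15
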