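# Phenotype XML record

`reporting.write_phenotype_xml` emits one XML document per condition: a
minimal, hierarchical, machine-readable record of the best-ranked fitted
model. The schema is intentionally small — an extension point towards
full digital-cell-line standards, not an implementation of one.

```xml
<?xml version='1.0' encoding='UTF-8'?>
<cell_phenotype_record version="1">
  <cell_line name="HCT116" media="McCoy's"/>
  <provenance tool="cellphenofit" tool_version="0.1.0" timestamp="...">
    <user name="..." contact="..."/>
  </provenance>
  <model name="live">
    <description>layperson description of the model</description>
    <parameters>
      <parameter name="growth_rate" units="1/h" value="0.0354..." sem="0.0017..."/>
      <parameter name="initial_live" units="cells" value="1000.0..." sem="..."/>
    </parameters>
    <metrics wsse="..." mape_percent="..." reduced_chi2="..."
             n_data="12" n_parameters="2"/>
  </model>
</cell_phenotype_record>
```

Rules:

* one `<parameter>` per fitted parameter; count equals the model's
  `n_parameters`;
* `value` and `sem` use Python float `repr`, so
  `reporting.read_phenotype_xml` recovers them bit-exactly;
* `sem` and `reduced_chi2` are omitted when the fit had no spare degrees
  of freedom;
* `timestamp` is the only field carrying wall-clock state; callers may
  pin it for byte-reproducible output.
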