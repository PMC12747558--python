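# Native model format (v1)

One metabolic model per file, plain tab-separated text, designed for
desk-scale debugging and bit-exact round-tripping.  SBML Level 3 (+fbc)
export/import exists for interoperability; the native file is the source
of truth.

```
# hydroscreen native model format v1
MODEL<TAB>model_id
OBJECTIVE<TAB>reaction_id
[METABOLITES]
id<TAB>name<TAB>compartment
...
[REACTIONS]
id<TAB>lower_bound<TAB>upper_bound<TAB>ec1;ec2<TAB>met:coeff;met:coeff
...
```

Rules:

* the header line is mandatory and versioned;
* `compartment` is `internal` or `external`;
* bounds and stoichiometric coefficients are written with `repr(float)`
  (shortest exact decimal), so write→read→write is byte-stable;
* the EC field may be empty (spontaneous/transport/exchange reactions);
  EC numbers are sorted and `;`-separated;
* stoichiometry entries are sorted by metabolite id; negative
  coefficients are consumption;
* blank lines and `#` comment lines are ignored;
* every stoichiometry metabolite must be declared in `[METABOLITES]` and
  an `OBJECTIVE` must be present — violations are parse errors naming
  the offending reaction/line.

Exchange reactions follow the standard constraint-based convention:
written as `external_metabolite →` (coefficient −1), negative flux is
uptake, and media open uptake by setting the lower bound to −rate.
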