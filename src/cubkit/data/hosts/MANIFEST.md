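# Host codon-usage tables — provenance

Every `*.synthetic.cusp` file in this directory is a **synthetic stand-in**,
not a snapshot of a codon-usage database. Each table was generated by the
package's own family-weight machinery (`cubkit.simulate`) from a generic
proteome-like amino-acid composition, a host-specific within-family skew,
and a GC3 tilt targeting the host's approximate third-position character:

| file | emulated host | GC3s target | profile seed |
|------|---------------|-------------|--------------|
| e_coli.synthetic.cusp | *Escherichia coli* | 0.55 | 11 |
| s_cerevisiae.synthetic.cusp | *Saccharomyces cerevisiae* | 0.38 | 12 |
| a_thaliana.synthetic.cusp | *Arabidopsis thaliana* | 0.42 | 13 |
| n_tabacum.synthetic.cusp | *Nicotiana tabacum* | 0.40 | 14 |
| t_aestivum.synthetic.cusp | *Triticum aestivum* | 0.60 | 15 |
| z_mays.synthetic.cusp | *Zea mays* | 0.55 | 16 |

They exercise the host-comparison machinery end to end (cusp parsing,
per-1000 scaling, divergence ratios and ranking). For real host-matching
decisions, replace them with current tables from a codon-usage database
(cusp format is read as-is via `cubkit.read_cusp`).
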