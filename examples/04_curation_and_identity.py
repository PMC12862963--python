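"""Curate a raw sequence set and summarise identity within/across groups.

The raw set mixes full-length TK regions with truncated (partial) entries;
curation removes keyword-flagged records, duplicates, and sequences that no
longer cover the kinase-domain anchors of the reference.
"""

from titinkit import curate, identity_summary
from titinkit.synth import SimConfig, simulate_families

cfg = SimConfig(seed=9, n_per_group=8, truncation_fraction=0.15)
sset, truth = simulate_families(cfg)

curated, report = curate(
    sset,
    exclude_keywords=["myosin light chain kinase", "LOW_QUALITY"],
    reference=truth.reference,
)
print(
    f"curation: kept {report.n_kept}/{report.n_input} "
    f"(keyword {report.n_removed_keyword}, duplicate "
    f"{report.n_removed_duplicate}, partial {report.n_removed_partial})"
)

summaries, cross = identity_summary(curated, group_by="group")
print("within-group identity (mean ± sd over all pairs):")
for s in summaries:
    print(f"  {s.group:22s} {s.mean_pct:5.1f} ± {s.sd_pct:4.1f}%  (n={s.n_sequences})")
print("cross-group identity, isoform a vs b (neoteleostei): "
      f"{cross.loc['a/neoteleostei', 'b/neoteleostei']:.1f}%")
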