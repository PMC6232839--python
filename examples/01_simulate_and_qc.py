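"""Generate a structured DArT panel and run the marker QC cascade.

The fixture plants exact numbers of duplicated, high-missing and low-MAF
markers, so the cascade's sequential counts are known in advance.
"""

import qtlome as q

G = q.gen_qc_fixture(n_total=1149, n_duplicate=46, n_high_missing=5,
                     n_low_maf=24, seed=11)
G_clean, report = q.run_qc(G)
print(f"{report.n_input} markers in")
print(f"  duplicated patterns removed : {len(report.removed_duplicates)}")
print(f"  >20% missing removed        : {len(report.removed_missing)}")
print(f"  MAF < 5% removed            : {len(report.removed_maf)}")
print(f"  retained                    : {report.n_retained}")

marker_map = q.fixture_map_for(G_clean.marker_ids, n_unmapped=202, seed=5)
G_mapped, report2 = q.run_qc(G, marker_map)
print(f"  with a map position         : {report2.n_retained}")
# The retained set is what the association scan operates on: markers that
# are unique, well-observed, polymorphic and genetically positioned.
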