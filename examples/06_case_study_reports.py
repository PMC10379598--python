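"""Reporting arithmetic on the bundled maize case-study counts.

Feeds the published per-stage transcript counts of a 15-library maize
survey (de novo and reference-based assemblies) through the cascade, class
and conservation report helpers; percentages are integer-truncated shares
of the input, as in the published tables.
"""

from lncannotate import case_counts, reports

print("cascade (de novo assembly):")
print(reports.cascade_report(case_counts.TRINITY_CASCADE).to_string(index=False))

print("\nlocation classes (de novo):")
print(
    reports.class_count_report(
        case_counts.TRINITY_CLASS_COUNTS, case_counts.TRINITY_KNOWN_LNCRNA
    ).to_string(index=False)
)

c = case_counts.TRINITY_CONSERVATION
print("\nconservation summary (de novo):")
print(
    reports.conservation_report(
        c["candidates"], c["homologous"], c["same_species"], c["other_species"]
    ).to_string(index=False)
)

tpl = reports.transcripts_per_locus(
    case_counts.TRINITY_CASCADE["lncRNA_candidate_transcripts"],
    case_counts.TRINITY_CASCADE["lncRNA_candidate_loci"],
)
print(f"\ntranscripts per lncRNA locus (de novo): {tpl:.2f}")
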