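"""Stage 4 — subdomain assignment and enrichment of prioritized variants.

NUP155's published structure divides into an N-terminal beta-propeller, the
crescent-shaped alpha-helical mid region, and a C-terminal alpha-helical
stack.  Exact residue boundaries are not published; the intervals used here
are ILLUSTRATIVE defaults (see docs/methods.md) and ship as an editable
config table.  Enrichment is an exact one-sided binomial against uniform
placement.

Writes results/domain_config.tsv, results/domain_assignment.tsv and
results/domain_enrichment.tsv.
"""

from pathlib import Path

from nupvar.domain_map import DomainInterval, assign_domains, domain_enrichment
from nupvar.synthetic_data import nup155_variants

RESULTS = Path(__file__).resolve().parents[1] / "results"
L = 1391

# illustrative boundaries: propeller through ~residue 510, crescent
# alpha-helical region through ~870, C-terminal stack beyond
DOMAINS = [
    DomainInterval("beta-propeller", 1, 510),
    DomainInterval("crescent-alpha", 511, 870),
    DomainInterval("c-terminal-stack", 871, 1391),
]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "domain_config.tsv").write_text(
        "name\tstart\tend\n"
        + "".join(f"{d.name}\t{d.start}\t{d.end}\n" for d in DOMAINS)
    )

    variants = nup155_variants()
    positions = [v.position for v in variants]
    labels = assign_domains(positions, DOMAINS, L=L)
    lines = ["protein_change\tposition\tdomain"]
    for v, lab in zip(variants, labels):
        lines.append(f"{v.protein_change}\t{v.position}\t{lab}")
    (RESULTS / "domain_assignment.tsv").write_text("\n".join(lines) + "\n")

    enr_lines = ["domain\tobserved\texpected\tp_value"]
    print(f"{len(positions)} variant positions against {len(DOMAINS)} "
          f"illustrative subdomain intervals:")
    for d in DOMAINS:
        e = domain_enrichment(positions, d, L=L)
        enr_lines.append(f"{e.domain}\t{e.observed}\t{e.expected:.3f}\t{e.p_value:.4g}")
        print(f"  {e.domain:18s} observed {e.observed:2d}  "
              f"expected {e.expected:5.2f}  binomial p = {e.p_value:.4g}")
    (RESULTS / "domain_enrichment.tsv").write_text("\n".join(enr_lines) + "\n")

    n_crescent = sum(1 for lab in labels if lab != "c-terminal-stack")
    print(f"{n_crescent} of {len(positions)} variants fall in the N-terminal "
          f"crescent region (propeller + alpha-helical) under these boundaries")


if __name__ == "__main__":
    main()
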