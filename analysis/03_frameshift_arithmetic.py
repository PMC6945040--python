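#!/usr/bin/env python
"""Frameshift truncation arithmetic for the two known SGK3 hairlessness alleles.

The Deerhound allele (c.137_138insT, p.(Glu47GlyfsTer3), 490-residue
protein) and the American Hairless Terrier allele (4-bp deletion,
p.Val96GlyfsTer50, premature stop reported at residue 157).  Writes the
computed retained/removed fractions to results/truncation_arithmetic.json.
"""

from __future__ import annotations

import json
from pathlib import Path

from mendelsieve.effect_annotation import premature_stop_fraction, truncation_fraction

RESULTS = Path(__file__).resolve().parent.parent / "results"
FULL_LENGTH = 490  # residues of the intact SGK3 protein


def main() -> None:
    deerhound = truncation_fraction("Glu47GlyfsTer3", FULL_LENGTH)
    print("Deerhound allele p.(Glu47GlyfsTer3):")
    print(f"  truncated protein : {deerhound.truncated_length} residues")
    print(
        f"  retained          : {deerhound.percent_retained:.1f}% "
        f"(~{deerhound.percent_retained_rounded}%)"
    )

    aht_fs = truncation_fraction("Val96GlyfsTer50", FULL_LENGTH)
    aht_reported = premature_stop_fraction(157, FULL_LENGTH)
    print("\nAHT allele p.Val96GlyfsTer50:")
    print(
        f"  standard fsTer arithmetic: stop at residue {aht_fs.truncated_length + 1}, "
        f"{aht_fs.percent_retained:.1f}% retained"
    )
    print(
        f"  with the reported stop at residue 157: removed "
        f"{aht_reported.removed_fraction:.3f} "
        f"(~{aht_reported.removed_nearest_third} of the protein)"
    )

    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "truncation_arithmetic.json").write_text(
        json.dumps(
            {
                "deerhound": {
                    "notation": "p.(Glu47GlyfsTer3)",
                    "truncated_length": deerhound.truncated_length,
                    "percent_retained": deerhound.percent_retained,
                    "percent_retained_rounded": deerhound.percent_retained_rounded,
                },
                "aht": {
                    "notation": "p.Val96GlyfsTer50",
                    "fster_truncated_length": aht_fs.truncated_length,
                    "reported_stop_residue": 157,
                    "removed_fraction_at_reported_stop": aht_reported.removed_fraction,
                    "removed_nearest_third": str(aht_reported.removed_nearest_third),
                },
                "full_length": FULL_LENGTH,
            },
            indent=2,
        )
        + "\n"
    )


if __name__ == "__main__":
    main()
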