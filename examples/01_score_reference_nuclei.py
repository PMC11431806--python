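"""Score the reference worked-example nuclei.

Each row is one nucleus with its published component values: the raw size
ratio (EPSize), the shape element and the appearance element.  The size
rule turns EPSize into ESize (0 below 0.5, identity to 1, saturating at
1), and the conditional harmonic mean aggregates the elements.  Rows with
ESize = 0 use the two-element branch.  Low HM ~ score-1 (near-benign)
nuclei, high HM ~ score-3.
"""

from pleoscore.features import e_size
from pleoscore.hm import harmonic_mean_score
from pleoscore.reference import WORKED_EXAMPLES

print(f"{'score':>5} {'EPSize':>8} {'ESize':>7} {'EShape':>7} {'EApp':>7} {'HM':>7}")
for ex in WORKED_EXAMPLES:
    es = e_size(ex.ep_size)
    hm = harmonic_mean_score(es, ex.e_shape, ex.e_appearance)
    print(
        f"{ex.score:>5} {ex.ep_size:>8.4f} {es:>7.4f} "
        f"{ex.e_shape:>7.4f} {ex.e_appearance:>7.4f} {hm:>7.4f}"
    )
print("\nHM rises with the pleomorphism score; the two rows with EPSize < 0.5")
print("drop the size element (two-element harmonic mean).")
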