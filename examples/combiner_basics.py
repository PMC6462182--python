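"""Combine two studies' evidence for single proteins, by hand.

Shows how signed two-sided p-values become one-sided p-values and how the
two directional combiners treat agreement, disagreement and one-sided
strength differently.
"""

from metacombine import (
    SignedPValue,
    one_sided_from_signed,
    pearson_combine,
    stouffer_combine,
)

cases = {
    "two studies agree (down in Group 1, p=0.02 each)": [(-1, 0.02), (-1, 0.02)],
    "studies contradict sharply": [(-1, 0.002), (1, 0.002)],
    "one strong study, one null": [(-1, 0.002), (0, 1.0)],
    "one strong study, one mildly opposed": [(-1, 0.002), (1, 0.4)],
}

for title, records in cases.items():
    p_lefts = [one_sided_from_signed(SignedPValue("P", s, p)) for s, p in records]
    sp, s_sign = stouffer_combine(p_lefts)
    pp, p_sign = pearson_combine(p_lefts)
    print(f"{title}")
    print(f"  one-sided p_L = {[round(p, 4) for p in p_lefts]}")
    print(f"  Stouffer: p = {sp:.5f}, sign = {s_sign:+d}")
    print(f"  Pearson:  p = {pp:.5f}, sign = {p_sign:+d}")
print(
    "\nA sign of -1 means the protein looks less abundant in Group 1; p is the\n"
    "combined two-sided p-value. Note Pearson keeps more of the strong study\n"
    "when the other study leans the opposite way (max of the two one-sided\n"
    "Fisher statistics), while Stouffer's Z-average dilutes it."
)
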