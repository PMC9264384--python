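"""Theoretical match/differ pattern of a fragment ladder.

For a 30-mer isomerized at residue 21, y fragments y1..y9 do not contain
the site (they match the reference standard) and y10..y29 do (they differ).
The pattern is a single step, and its position maps back to the residue:
site = L - n* + 1 for the first differing y fragment n*.
"""

from isolocate import expected_pattern, fragment_mz, Peptide

L, site = 30, 21
for series in ("y", "b"):
    pat = expected_pattern(L, site, series)
    first_differ = int(pat.argmax()) + 1 if pat.any() else None
    print(f"{series} series: "
          + "".join("D" if p else "m" for p in pat)
          + f"   first differing fragment: {series}{first_differ}")

pep = Peptide(length=8, sequence="AGDKSEDK", iso_site=7)
print("\nmonoisotopic m/z of y1..y3 for AGDKSEDK (z=1):",
      [round(fragment_mz(pep, "y", n, 1), 4) for n in (1, 2, 3)])
print("isoAsp carries zero mass: the isomer ladder is isobaric, which is")
print("why localization needs ion mobility rather than m/z.")
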