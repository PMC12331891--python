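"""How many genotypes can deletions + inversions reach in a loxPsym module?

Counts the signed-arrangement design space for module sizes 1..7 and checks
the closed form against the brute-force event-closure oracle at small n.
"""

from scramblekit import count_del_inv_space, verify_closed_form

print("BFS oracle vs closed form (small modules):")
print(verify_closed_form(4).to_string(index=False))

print("\nclosed-form design space by module size:")
for n in range(1, 8):
    print(f"  n={n}: {count_del_inv_space(n):>9,} genotypes")

# The 7-gene HIS module (8 loxPsym sites) can reach 1,063,623 distinct
# genotypes by deletions and inversions alone -- the combinatorial pool an
# exhaustive screen would have to cover.
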