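"""The leading-eight norms and collective group assessment.

Prints the full assessment/action table of a norm, then reproduces the
canonical disagreement scenario: a donor and an outside observer judge the
same recipient group differently because they hold different private
opinions of its members.
"""

from collrep import collective_reputation, leading_eight_table

table = leading_eight_table("Stern Judging")  # alias for L6
print(f"Strategy {table.id} (Stern Judging)")
print("  assessment (donor rep, group rep, action) -> new rep:")
for key, value in sorted(table.assessment.items(), reverse=True):
    ra, rp, b = key
    print(f"    ({'G' if ra else 'B'}, {'G' if rp else 'B'}, {'C' if b else 'D'})"
          f" -> {'G' if value else 'B'}")
print("  action (self rep, group rep) -> action:")
for key, value in sorted(table.action.items(), reverse=True):
    ra, rp = key
    print(f"    ({'G' if ra else 'B'}, {'G' if rp else 'B'})"
          f" -> {'C' if value else 'D'}")

# A 5-player group: donor 0 faces recipients 1..4.  The donor deems three of
# the four recipients good; an outside observer deems only two good.
recipients = [1, 2, 3, 4]
donor_row = [1, 1, 1, 1, 0]
observer_row = [1, 0, 1, 1, 0]
lam = 0.7

donor_view = collective_reputation(donor_row, recipients, lam)
observer_view = collective_reputation(observer_row, recipients, lam)
print(f"\nGroup assessment at criterion lam = {lam}:")
print(f"  donor sees 3/4 good    -> group {'good' if donor_view else 'bad'}")
print(f"  observer sees 2/4 good -> group {'good' if observer_view else 'bad'}")
print("The same cooperative act will therefore raise the donor's standing in"
      "\nits own eyes but can spoil it in the observer's eyes.")
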