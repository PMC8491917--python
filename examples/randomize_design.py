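"""Block-randomized allocation of tendon halves to technique groups.

Six porcine hind limbs, four extensor tendons each: the small-caliber
lateral (I) and medial (IV) tendons serve as donors, the median tendons
(II, III) as recipients. The plan pairs a proximal with a distal half per
suture and is balanced by construction: equal group sizes and every
donor x recipient combination equally often per group.
"""

from tenomech import block_randomize, validate_plan

groups = ("PT", "FR", "WF")
plan = block_randomize(n_limbs=6, groups=groups, seed=2026)

print(plan.to_string(index=False, max_rows=12))
print(f"...\n{plan.suture_id.nunique()} sutures from 6 limbs")
print("per-group counts:", plan[plan.role == "donor"].group.value_counts().to_dict())
problems = validate_plan(plan, groups)
print("independent balance check:", "passed" if not problems else problems)
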