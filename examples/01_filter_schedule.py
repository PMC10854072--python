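"""Filter-width calculus: how one level's width budget is split.

Each level gets a budget M = beta * F (F = matched U-Net stage width,
beta = 1.56) which is split 1/6 : 1/3 : 1/2 across the block's three
chained 3x3 convolutions; the 1x1 residual projection gets their sum.
"""

from mducnn import (ScheduleConfig, allocate_block_filters, level_width,
                    path_plan, table_literal_schedule)

cfg = ScheduleConfig(mode="formula")
print("level  F     M        3x3 triple        1x1 residual")
for i, F in enumerate(cfg.base_filters, start=1):
    M = level_width(cfg.beta, F)
    a = allocate_block_filters(M, cfg, level=i)
    print(f"{i:>5}  {F:<4}  {M:<7.2f}  {str(a.conv3_filters):<16}  {a.res1_filters}")

print("\npublished five-level schedule (normative residual = triple sum):")
for a in table_literal_schedule():
    print(f"  level {a.level}: {a.conv3_filters}, residual {a.res1_filters} "
          f"(printed {a.printed_res1})")

plan = path_plan(4, [32, 64, 128, 256])
print(f"\nskip paths: unit counts {plan.unit_counts}, widths {plan.unit_widths}")
print("(shallow skips get more residual units: their features are farther,")
print(" semantically, from the decoder features they are concatenated with)")
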