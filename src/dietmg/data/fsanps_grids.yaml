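# FSA-NPS point-attribution grids (per 100 g of food or drink).
# A component earns the number of points attached to the highest breakpoint
# it strictly exceeds.  Unfavorable components score 0-10 points, favorable
# components 0-5; the item score is unfavorable minus favorable, spanning
# -15 (most healthy) to +40 (least healthy).
unfavorable:
  energy_kj:
    breakpoints: [335, 670, 1005, 1340, 1675, 2010, 2345, 2680, 3015, 3350]
  sugars_g:
    breakpoints: [4.5, 9.0, 13.5, 18.0, 22.5, 27.0, 31.0, 36.0, 40.0, 45.0]
  saturated_fat_g:
    breakpoints: [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0]
  sodium_mg:
    breakpoints: [90, 180, 270, 360, 450, 540, 630, 720, 810, 900]
favorable:
  fiber_g:
    breakpoints: [0.9, 1.9, 2.8, 3.7, 4.7]
  protein_g:
    breakpoints: [1.6, 3.2, 4.8, 6.4, 8.0]
  fruit_veg_pct:
    breakpoints: [40, 60, 80]
    points: [1, 2, 5]
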