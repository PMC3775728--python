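"""Call AChA occlusion from CBV maps, blinded to ground truth.

The classifier excludes large-vessel voxels (CBV > 10 ml/100 g), computes
the mean contralateral CBV, and calls the AChA occluded when no ipsilateral
AChA-territory voxel reaches that mean on the caudal slice.
"""

from achastroke import (
    CohortConfig,
    build_atlas,
    classify_achao,
    generate_cbv_maps,
    generate_cohort,
)

atlas = build_atlas()
cfg = CohortConfig()
records = generate_cohort(cfg, seed=1)

shown = {True: False, False: False}
correct = 0
for rec in records:
    maps = generate_cbv_maps(rec, atlas, cfg, seed=1)
    res = classify_achao(maps, atlas)
    correct += res.acha_occluded == rec.acha_occluded
    if not shown[rec.acha_occluded]:
        shown[rec.acha_occluded] = True
        print(f"{rec.animal_id}: truth AChAo={rec.acha_occluded}")
        print(f"  mean contralateral CBV  {res.mean_contralateral_cbv:.2f} ml/100 g")
        print(f"  vessel voxels excluded  {res.excluded_vessel_voxels}")
        print(f"  AChA voxels >= mean     {res.supra_threshold_voxels_in_acha}")
        print(f"  call: {'occluded' if res.acha_occluded else 'patent'}\n")

print(f"blinded call matches planted truth in {correct}/{len(records)} animals")
print("(a patent AChA shows supra-threshold signal in its territory;")
print(" an occluded one shows none)")
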