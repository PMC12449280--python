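[
 {"class_name": "lung_left", "lo": -800, "hi": -600, "min_component_mm3": 1000, "side_constraint": "left_of_midline", "priority": 5},
 {"class_name": "lung_right", "lo": -800, "hi": -600, "min_component_mm3": 1000, "side_constraint": "right_of_midline", "priority": 5},
 {"class_name": "fat", "lo": -160, "hi": -80, "min_component_mm3": 1000, "side_constraint": "none", "priority": 4},
 {"class_name": "gallbladder", "lo": -75, "hi": -12, "min_component_mm3": 200, "side_constraint": "none", "priority": 6},
 {"class_name": "muscle", "lo": 100, "hi": 180, "min_component_mm3": 500, "side_constraint": "none", "priority": 4},
 {"class_name": "liver", "lo": 190, "hi": 290, "min_component_mm3": 1000, "side_constraint": "none", "priority": 4},
 {"class_name": "spleen", "lo": 290, "hi": 390, "min_component_mm3": 500, "side_constraint": "none", "priority": 4},
 {"class_name": "kidney_left", "lo": 395, "hi": 452, "min_component_mm3": 300, "side_constraint": "left_of_midline", "priority": 8},
 {"class_name": "kidney_right", "lo": 395, "hi": 452, "min_component_mm3": 300, "side_constraint": "right_of_midline", "priority": 8},
 {"class_name": "tumor", "lo": 462, "hi": 550, "min_component_mm3": 250, "side_constraint": "none", "priority": 7},
 {"class_name": "aorta", "lo": 560, "hi": 720, "min_component_mm3": 300, "side_constraint": "none", "priority": 6},
 {"class_name": "bone", "lo": 850, "hi": 1150, "min_component_mm3": 500, "side_constraint": "none", "priority": 3}
]
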