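{
  "primary": [
    {"module": "head_and_brain", "keywords": ["concussion", "craniocerebral injury", "brain contusion", "intracranial hematoma"], "weight": 5},
    {"module": "neck", "keywords": ["cervical spine injury", "cervical spine fracture", "neck laceration"], "weight": 1},
    {"module": "thorax", "keywords": ["rib fracture", "lung contusion", "pneumothorax", "hemothorax"], "weight": 2},
    {"module": "abdomen", "keywords": ["abdominal hemorrhage", "splenic rupture", "liver laceration", "bowel perforation"], "weight": 3},
    {"module": "limb_pelvis_fracture", "keywords": ["fracture", "fracture reduction", "pelvic fracture", "femoral fracture"], "weight": 1},
    {"module": "spine_spinal_cord", "keywords": ["spinal fracture", "spinal cord injury", "vertebral dislocation"], "weight": 3},
    {"module": "multiple_injuries", "keywords": ["multiple trauma", "multi-site injury", "polytrauma"], "weight": 5}
  ],
  "other": [
    {"module": "hemorrhagic", "keywords": ["hematoma", "internal bleeding", "hemorrhagic shock"], "weight": 5},
    {"module": "organ_injury", "keywords": ["liver injury", "kidney injury", "splenic injury"], "weight": 1},
    {"module": "cardiovascular", "keywords": ["heart injury", "pericardial effusion", "aortic injury"], "weight": 5},
    {"module": "soft_tissue", "keywords": ["muscle injury", "ligament tear", "skin avulsion"], "weight": 1},
    {"module": "fracture", "keywords": ["open fracture", "closed fracture", "comminuted fracture"], "weight": 1},
    {"module": "vertebra", "keywords": ["spinal cord injury", "nerve injury", "vertebral compression"], "weight": 1},
    {"module": "underlying_disease", "keywords": ["diabetes", "high blood pressure", "coronary heart disease", "anticoagulant use"], "weight": 4}
  ]
}
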