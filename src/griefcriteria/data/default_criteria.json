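{
  "_comment": "Reconstructed default symptom-to-item mapping for the four proposed persistent-grief criteria sets. The published item-matching tables are not reproduced here; this mapping preserves the k-of-m structure (PCBD 6/12, PGD_PLOS 5/9, CG 2/8, ICD11_PGD 1/7), the shared core symptoms, and the nesting of the sets: coarser criteria use broader symptom categories whose item sets union the items of the finer symptoms they subsume. Replace with a study-specific mapping as needed.",
  "criteria_sets": [
    {
      "name": "PCBD",
      "min_core": 1,
      "min_associated": 6,
      "require_impairment": true,
      "min_months_since_death": 12.0,
      "core_symptoms": [
        {"symptom_id": "yearning_longing", "mapped_items": ["cgq_01"]},
        {"symptom_id": "preoccupation_with_deceased", "mapped_items": ["cgq_02"]}
      ],
      "associated_symptoms": [
        {"symptom_id": "disbelief_about_death", "mapped_items": ["cgq_03"]},
        {"symptom_id": "anger_bitterness", "mapped_items": ["cgq_04"]},
        {"symptom_id": "avoidance_of_reminders", "mapped_items": ["cgq_05"]},
        {"symptom_id": "difficulty_trusting_others", "mapped_items": ["cgq_06"]},
        {"symptom_id": "feeling_alone_detached", "mapped_items": ["cgq_07"]},
        {"symptom_id": "meaninglessness_without_deceased", "mapped_items": ["cgq_08"]},
        {"symptom_id": "confusion_about_role_in_life", "mapped_items": ["cgq_09"]},
        {"symptom_id": "difficulty_pursuing_interests", "mapped_items": ["cgq_10"]},
        {"symptom_id": "emotional_numbness", "mapped_items": ["cgq_11"]},
        {"symptom_id": "self_blame_about_death", "mapped_items": ["cgq_12"]},
        {"symptom_id": "desire_to_die_to_join_deceased", "mapped_items": ["cgq_13"]},
        {"symptom_id": "difficulty_positive_reminiscing", "mapped_items": ["cgq_14"]}
      ]
    },
    {
      "name": "PGD_PLOS",
      "min_core": 1,
      "min_associated": 5,
      "require_impairment": true,
      "min_months_since_death": 12.0,
      "core_symptoms": [
        {"symptom_id": "yearning_longing", "mapped_items": ["cgq_01"]},
        {"symptom_id": "preoccupation_with_deceased", "mapped_items": ["cgq_02"]}
      ],
      "associated_symptoms": [
        {"symptom_id": "difficulty_accepting_death", "mapped_items": ["cgq_03", "cgq_12"]},
        {"symptom_id": "anger_bitterness_over_loss", "mapped_items": ["cgq_04", "cgq_13"]},
        {"symptom_id": "avoidance_of_reminders", "mapped_items": ["cgq_05", "cgq_14"]},
        {"symptom_id": "difficulty_trusting_others", "mapped_items": ["cgq_06", "cgq_12"]},
        {"symptom_id": "loneliness_detachment", "mapped_items": ["cgq_07", "cgq_13"]},
        {"symptom_id": "meaninglessness", "mapped_items": ["cgq_08", "cgq_14"]},
        {"symptom_id": "role_confusion", "mapped_items": ["cgq_09", "cgq_12"]},
        {"symptom_id": "diminished_engagement", "mapped_items": ["cgq_10", "cgq_13"]},
        {"symptom_id": "emotional_numbness", "mapped_items": ["cgq_11", "cgq_14"]}
      ]
    },
    {
      "name": "CG",
      "min_core": 1,
      "min_associated": 2,
      "require_impairment": true,
      "min_months_since_death": 12.0,
      "core_symptoms": [
        {"symptom_id": "yearning_longing", "mapped_items": ["cgq_01"]},
        {"symptom_id": "preoccupation_with_deceased", "mapped_items": ["cgq_02"]}
      ],
      "associated_symptoms": [
        {"symptom_id": "difficulty_accepting_death", "mapped_items": ["cgq_03", "cgq_12"]},
        {"symptom_id": "anger_bitterness_over_loss", "mapped_items": ["cgq_04", "cgq_13"]},
        {"symptom_id": "avoidance_of_reminders", "mapped_items": ["cgq_05", "cgq_14"]},
        {"symptom_id": "difficulty_trusting_others", "mapped_items": ["cgq_06", "cgq_12"]},
        {"symptom_id": "loneliness_detachment", "mapped_items": ["cgq_07", "cgq_13"]},
        {"symptom_id": "meaninglessness", "mapped_items": ["cgq_08", "cgq_14"]},
        {"symptom_id": "role_confusion", "mapped_items": ["cgq_09", "cgq_12"]},
        {"symptom_id": "withdrawal_and_numbness", "mapped_items": ["cgq_10", "cgq_11", "cgq_13", "cgq_14"]}
      ]
    },
    {
      "name": "ICD11_PGD",
      "min_core": 1,
      "min_associated": 1,
      "require_impairment": true,
      "min_months_since_death": 12.0,
      "core_symptoms": [
        {"symptom_id": "yearning_longing", "mapped_items": ["cgq_01"]},
        {"symptom_id": "preoccupation_with_deceased", "mapped_items": ["cgq_02"]}
      ],
      "associated_symptoms": [
        {"symptom_id": "difficulty_accepting_death", "mapped_items": ["cgq_03", "cgq_12"]},
        {"symptom_id": "anger_bitterness_over_loss", "mapped_items": ["cgq_04", "cgq_13"]},
        {"symptom_id": "avoidance_of_reminders", "mapped_items": ["cgq_05", "cgq_14"]},
        {"symptom_id": "difficulty_trusting_others", "mapped_items": ["cgq_06", "cgq_12"]},
        {"symptom_id": "loneliness_detachment", "mapped_items": ["cgq_07", "cgq_13"]},
        {"symptom_id": "meaninglessness", "mapped_items": ["cgq_08", "cgq_14"]},
        {"symptom_id": "emotional_pain_and_withdrawal", "mapped_items": ["cgq_09", "cgq_10", "cgq_11", "cgq_12", "cgq_13", "cgq_14"]}
      ]
    }
  ]
}
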