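id: goal
label: Information needs of patients with a rare disease
children:
  - id: medical
    label: Information about medical questions
    children:
      - id: diagnostics
        label: Information about diagnostics
      - id: therapy
        label: Information about therapy
      - id: disease_pattern
        label: Information about disease patterns
  - id: research
    label: Information about research
    children:
      - id: new_studies
        label: Information about new studies
      - id: study_results
        label: Information about study results
      - id: registers
        label: Information about registers
  - id: current_events
    label: Information about current events
  - id: social
    label: Information about social counselling and assistance services
    children:
      - id: social_legal
        label: Information about social-legal advice
      - id: psychosocial
        label: Information about psychosocial counselling
      - id: self_help
        label: Information about self-help
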