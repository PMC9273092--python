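name	domain	potential	social_elevated	display_name
married	surrogate_decision_makers	reduced	0	Married
partnered	surrogate_decision_makers	reduced	0	Partnered
relatives_unknown_involvement	surrogate_decision_makers	reduced	0	Living relatives with unknown involvement
caregiver_support	surrogate_decision_makers	reduced	0	Caregiver support
living_with_others	surrogate_decision_makers	reduced	0	Living with or close to others
community_connection	surrogate_decision_makers	reduced	0	Community connection
religious_connections	surrogate_decision_makers	reduced	0	Religious connections
surrogate_identified	surrogate_decision_makers	reduced	0	Surrogate decision maker identified
unmarried	surrogate_decision_makers	elevated	1	Unmarried
living_alone	surrogate_decision_makers	elevated	1	Living alone
transitionally_situated	surrogate_decision_makers	elevated	1	Transitionally situated
surrogate_unidentified	surrogate_decision_makers	elevated	1	Surrogate decision maker unidentified
palliative_care	advance_directives	reduced	0	Palliative care
hospice	advance_directives	reduced	0	Hospice
advance_directives_available	advance_directives	reduced	0	Advance directives available
advance_directives_unavailable	advance_directives	elevated	1	Advance directives unavailable
lacking_capacity	decisional_capacity	elevated	0	Lacking capacity
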