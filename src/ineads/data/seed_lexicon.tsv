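term	subcategory	provenance
husband	married	seed
wife	married	seed
spouse	married	seed
girlfriend	partnered	seed
boyfriend	partnered	seed
significant other	partnered	seed
fiancé	partnered	seed
fiancée	partnered	seed
domestic partner	partnered	seed
son	relatives_unknown_involvement	seed
daughter	relatives_unknown_involvement	seed
aunt	relatives_unknown_involvement	seed
uncle	relatives_unknown_involvement	seed
brother	relatives_unknown_involvement	seed
sister	relatives_unknown_involvement	seed
nephew	relatives_unknown_involvement	seed
niece	relatives_unknown_involvement	seed
complicated family dynamics	relatives_unknown_involvement	seed
primary caregiver	caregiver_support	seed
sole caregiver	caregiver_support	seed
main caregiver	caregiver_support	seed
roommate	living_with_others	seed
lives with	living_with_others	seed
lives with roommate	living_with_others	seed
lives with family	living_with_others	seed
daughter lives nearby	living_with_others	seed
supportive neighbors	community_connection	seed
friend who assists	community_connection	seed
senior center	community_connection	seed
supportive friends	community_connection	seed
attends senior center	community_connection	seed
their rabbi	religious_connections	seed
clergy involved	religious_connections	seed
practicing catholic	religious_connections	seed
chaplain	religious_connections	seed
pastor	religious_connections	seed
sacrament of the sick	religious_connections	seed
family meeting occurred	surrogate_identified	seed
family meeting held	surrogate_identified	seed
spoke with daughter	surrogate_identified	seed
spoke with son	surrogate_identified	seed
family decided	surrogate_identified	seed
next of kin contacted	surrogate_identified	seed
recently widowed	unmarried	seed
estranged from his wife	unmarried	seed
never married	unmarried	seed
widowed	unmarried	seed
divorced	unmarried	seed
unmarried	unmarried	seed
lives alone	living_alone	seed
lives independently	living_alone	seed
without caregiver	living_alone	seed
lives by himself	living_alone	seed
lives by herself	living_alone	seed
alone at home	living_alone	seed
currently homeless	transitionally_situated	seed
homeless	transitionally_situated	seed
half-way house	transitionally_situated	seed
halfway house	transitionally_situated	seed
incarcerated	transitionally_situated	seed
shelter	transitionally_situated	seed
undomiciled	transitionally_situated	seed
cannot find family	surrogate_unidentified	seed
family member did not respond	surrogate_unidentified	seed
family unreachable	surrogate_unidentified	seed
no contact from family	surrogate_unidentified	seed
unable to reach family	surrogate_unidentified	seed
no known family	surrogate_unidentified	seed
palliative care	palliative_care	seed
palliative services	palliative_care	seed
palliative care consulted	palliative_care	seed
ethics palliative care	palliative_care	seed
comfort measures only	palliative_care	seed
comfort care	palliative_care	seed
hospice	hospice	seed
home hospice	hospice	seed
hospice nurses	hospice	seed
arrange home hospice	hospice	seed
moving toward hospice	hospice	seed
hospice referral	hospice	seed
health care proxy appointed	advance_directives_available	seed
healthcare proxy appointed	advance_directives_available	seed
sister hcp	advance_directives_available	seed
contact daughter hcp	advance_directives_available	seed
code status dnr dni	advance_directives_available	seed
dnr dni	advance_directives_available	seed
living will on file	advance_directives_available	seed
advance directive on file	advance_directives_available	seed
molst completed	advance_directives_available	seed
polst completed	advance_directives_available	seed
no living will	advance_directives_unavailable	seed
no advance directives	advance_directives_unavailable	seed
no healthcare proxy	advance_directives_unavailable	seed
no hcp	advance_directives_unavailable	seed
no molst on file	advance_directives_unavailable	seed
aox disoriented	lacking_capacity	seed
loss of executive function	lacking_capacity	seed
impaired judgement	lacking_capacity	seed
dementia	lacking_capacity	seed
severe dementia	lacking_capacity	seed
lacks capacity	lacking_capacity	seed
altered mental status	lacking_capacity	seed
unable to make decisions	lacking_capacity	seed
obtunded	lacking_capacity	seed
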