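name	value	unit	lower	upper	source
pop_0_14_2011	1370000	persons	1000000	1800000	assumed
pop_15_24_2011	950000	persons	700000	1200000	assumed
pop_25p_2011	4900000	persons	4000000	6000000	assumed
entry_children	95000	persons/year	50000	150000	assumed
entry_adults	85000	persons/year	0	200000	assumed
ageing_0_14	0.06666666667	1/year	0.05	0.1	assumed
ageing_15_24	0.1	1/year	0.08	0.12	assumed
exit_0_14	0.002	1/year	0	0.01	assumed
exit_15_24	0.004	1/year	0	0.01	assumed
exit_25p	0.0155	1/year	0.005	0.03	assumed
init_prev_0_14	20	%	5	40	calibrated
init_prev_15_24	29	%	10	50	calibrated
init_prev_25p	26	%	10	45	calibrated
init_frac_waiting	0.02	fraction of distressed	0	0.2	assumed
init_frac_gp	0.05	fraction of distressed	0	0.3	assumed
init_frac_spec	0.04	fraction of distressed	0	0.3	assumed
init_frac_diseng	0.06	fraction of distressed	0	0.3	assumed
init_frac_recov	0.02	fraction of low-distress	0	0.2	assumed
onset_0_14	0.14	1/year	0.01	0.6	calibrated
onset_15_24	0.42	1/year	0.02	1.2	calibrated
onset_25p	0.18	1/year	0.02	0.8	calibrated
onset_trend	0.27	fraction/year	0	0.6	calibrated
onset_trend_end	2019	decimal year	2015	2022	assumed
remission	0.45	1/year	0.05	2	calibrated
perceived_need	0.55	fraction	0.1	1	calibrated
help_seek_rate	0.7213	1/year	0.1	3	calibrated
seek_trend	0.02	fraction/year	0	0.05	calibrated
seek_trend_end	2022	decimal year	2015	2029	assumed
gp_referral_fraction	0.517	fraction	0.1	0.9	calibrated
gp_recovery	1.2	1/year	0.2	6	assumed
gp_return	1.8	1/year	0.1	6	assumed
sessions_per_user	4.5	sessions/user	1	10	supplementary
treatment_recovery	4	1/year	0.5	12	assumed
intake_sessions	1	sessions/admission	0	5	assumed
admit_time	0.02	years	0.01	0.25	assumed
cap_demand_elasticity	0.15	dimensionless	0	1	assumed
capacity_2011	2550300	sessions/year	1000000	10000000	calibrated
capacity_slope	120922	sessions/year^2	10000	1000000	calibrated
wait_ref	4	weeks	1	26	assumed
wait_cap	104	weeks	26	208	assumed
disengage_coeff	0.025	1/week	0.001	0.5	calibrated
reengage_rate	0.8	1/year	0.1	4	assumed
reengage_seek_rate	4	1/year	0	6	assumed
recovery_fade	1.5	1/year	0.2	6	assumed
ed_rate_0_14	0.0195773	events/person/year	0.0001	0.2	calibrated
ed_rate_15_24	0.0393437	events/person/year	0.0001	0.3	calibrated
ed_rate_25p	0.029366	events/person/year	0.0001	0.3	calibrated
selfharm_rate_0_14	0.00108662	events/person/year	1e-06	0.05	calibrated
selfharm_rate_15_24	0.00511974	events/person/year	1e-06	0.05	calibrated
selfharm_rate_25p	0.00227202	events/person/year	1e-06	0.05	calibrated
suicide_rate_0_14	1.16789e-05	events/person/year	1e-08	0.01	calibrated
suicide_rate_15_24	0.000245818	events/person/year	1e-08	0.01	calibrated
suicide_rate_25p	0.0003601	events/person/year	1e-08	0.01	calibrated
outmult_waiting	1.15	dimensionless	1	3	assumed
outmult_gp	0.85	dimensionless	0.1	1	assumed
outmult_spec	0.45	dimensionless	0.1	1	assumed
diseng_escalation	1.6	dimensionless	1	5	calibrated
covid_onset_mult_peak	1.3	dimensionless	1	2	assumed
covid_onset_mult_late	1.15	dimensionless	1	2	assumed
covid_employment_onset	0.1	dimensionless	0	1	assumed
jobkeeper_damping	0.5	dimensionless	0	1	assumed
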